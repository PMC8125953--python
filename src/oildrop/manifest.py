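"""Benchmark manifest: scoring published structure sets against printed RD values.

The packaged manifest encodes the analysis units of the published RD survey
(whole chains, domains, in-complex chains, interface domains).  ``run_report``
resolves each entry against locally cached structure files — optionally
fetching them from RCSB by accession when explicitly asked — computes RD,
and tabulates it next to the printed reference with the absolute deviation.
Entries whose units cannot be expressed in the selector grammar are flagged
and skipped rather than aborting the run.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.request
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import OildropError
from .fod_core import DEFAULT_CUTOFF, rd_score
from .structure_io import read_structure, select_unit

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def load_packaged_manifest() -> dict:
    with resources.files("oildrop.data").joinpath("benchmark_manifest.json").open() as fh:
        return json.load(fh)


def load_manifest(path: str | Path | None = None) -> dict:
    if path is None:
        return load_packaged_manifest()
    return json.loads(Path(path).read_text())


def fetch_structure(pdb_id: str, cache_dir: str | Path, timeout: float = 60.0) -> Path:
    """Download a PDB entry into the cache directory (explicit opt-in only)."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    target = cache_dir / f"{pdb_id.upper()}.pdb"
    if target.exists():
        return target
    url = RCSB_URL.format(pdb_id=pdb_id.upper())
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            target.write_bytes(resp.read())
    except (urllib.error.URLError, OSError) as exc:
        raise OildropError(f"could not fetch {pdb_id} from {url}: {exc}") from exc
    return target


def locate_structure(pdb_id: str, cache_dir: str | Path, fetch: bool = False) -> Path | None:
    """Find a cached structure file, fetching it only when ``fetch`` is set."""
    cache_dir = Path(cache_dir)
    for pattern in (f"{pdb_id.upper()}.pdb", f"{pdb_id.lower()}.pdb",
                    f"{pdb_id.upper()}.cif", f"{pdb_id.lower()}.cif"):
        candidate = cache_dir / pattern
        if candidate.exists():
            return candidate
    if fetch:
        return fetch_structure(pdb_id, cache_dir)
    return None


def run_report(
    manifest: dict,
    cache_dir: str | Path,
    fetch: bool = False,
    scale: str = "kyte-doolittle",
    cutoff_c: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Score every manifest entry; one row per entry, errors isolated.

    Rows carry the computed RD beside the printed reference and the absolute
    deviation; entries that cannot run (missing structure without ``fetch``,
    null or unresolvable selector) get a status message instead of a value.
    """
    rows = []
    models: dict[str, object] = {}
    for entry in manifest["entries"]:
        pdb_id = entry["structure"]
        row = {
            "table": entry.get("table"),
            "structure": pdb_id,
            "label": entry.get("label", ""),
            "unit": entry.get("unit"),
            "envelope_source": entry.get("envelope_source", "self"),
            "reference_rd": entry.get("reference_rd"),
            "rd": None,
            "abs_deviation": None,
            "n": None,
            "status": "",
        }
        try:
            if entry.get("unit") is None:
                raise OildropError(entry.get("note", "unit not expressible; skipped"))
            if pdb_id not in models:
                path = locate_structure(pdb_id, cache_dir, fetch=fetch)
                if path is None:
                    raise OildropError(
                        f"structure {pdb_id} not cached in {cache_dir}; "
                        "pass --fetch to download it"
                    )
                from .structure_io import assign_hydrophobicity, read_hydrophobicity_sidecar

                overrides = None
                sidecar = path.with_suffix(path.suffix + ".hyd")
                if sidecar.exists():
                    overrides = read_hydrophobicity_sidecar(sidecar)
                models[pdb_id] = assign_hydrophobicity(
                    read_structure(path), scale, overrides=overrides
                )
            model = models[pdb_id]
            unit = select_unit(model, entry["unit"])
            parent = (
                select_unit(model, entry["parent"])
                if entry.get("envelope_source") == "parent"
                else None
            )
            result = rd_score(
                unit,
                envelope_source=entry.get("envelope_source", "self"),
                parent_unit=parent,
                cutoff_c=cutoff_c,
            )
            row["rd"] = round(result.rd, 4)
            row["n"] = result.n_residues
            if entry.get("reference_rd") is not None:
                row["abs_deviation"] = round(abs(result.rd - entry["reference_rd"]), 4)
            row["status"] = "ok" + (" (approximate unit)" if entry.get("approximate") else "")
        except OildropError as exc:
            row["status"] = f"skipped: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
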