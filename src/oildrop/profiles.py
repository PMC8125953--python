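"""Per-residue T/O profile tables and figures.

Profiles are the model's main diagnostic: plotting the theoretical (T) and
observed (O) distributions against residue index shows *where* a unit
departs from the idealized core — interface patches, ligand pockets, or
exposed hydrophobic fragments appear as localized T/O mismatches.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError
from .fod_core import DEFAULT_CUTOFF, EnvelopeSource, hydro_profile
from .structure_io import ResidueKey, ResidueRecord

CSV_COLUMNS = [
    "index", "chain", "seq", "icode", "aa", "T", "O", "deviation", "flags",
]


def profile_table(
    unit: Sequence[ResidueRecord],
    envelope_source: EnvelopeSource = "self",
    parent_unit: Sequence[ResidueRecord] | None = None,
    cutoff_c: float = DEFAULT_CUTOFF,
    flags: dict[str, Iterable[ResidueKey]] | None = None,
) -> pd.DataFrame:
    """One row per residue with T, O, deviation O - T, and subset flags.

    ``flags`` maps a label (e.g. "interface", "ligand", "eliminated") to
    the residue keys carrying it; a residue's flags cell joins its labels
    with ``;``.  Deviations sum to zero over the unit because both
    distributions are normalized.
    """
    prof = hydro_profile(
        unit, envelope_source=envelope_source, parent_unit=parent_unit,
        cutoff_c=cutoff_c,
    )
    flags = flags or {}
    rows = []
    for i, r in enumerate(unit):
        labels = sorted(label for label, keys in flags.items() if r.key in set(keys))
        rows.append(
            {
                "index": i,
                "chain": r.chain_id,
                "seq": r.seq_number,
                "icode": r.insertion_code,
                "aa": r.aa_type,
                "T": prof.T[i],
                "O": prof.O[i],
                "deviation": prof.O[i] - prof.T[i],
                "flags": ";".join(labels),
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def render_profile(
    rows: pd.DataFrame,
    output_path: str | Path,
    format: str = "csv",
    title: str = "",
) -> Path:
    """Write a profile table as CSV, or plot T and O traces to png/svg.

    Plotting requires matplotlib; the CSV path never does.
    """
    if rows.empty:
        raise ConfigurationError("empty profile table")
    output_path = Path(output_path)
    output_path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        rows.to_csv(output_path, index=False, float_format="%.12g")
        return output_path
    if format in ("png", "svg"):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(6.0, len(rows) / 25.0), 3.5))
        ax.plot(rows["index"], rows["T"], color="tab:blue", label="T (idealized)")
        ax.plot(rows["index"], rows["O"], color="tab:red", label="O (observed)")
        for label, color in (("interface", "pink"), ("ligand", "gold")):
            mask = rows["flags"].str.contains(label, na=False)
            if mask.any():
                ax.scatter(
                    rows.loc[mask, "index"], rows.loc[mask, "O"],
                    s=12, color=color, zorder=3, label=label,
                )
        ax.set_xlabel("residue index in unit")
        ax.set_ylabel("normalized hydrophobicity")
        if title:
            ax.set_title(title)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(output_path)
        plt.close(fig)
        return output_path
    raise ConfigurationError(f"unknown output format {format!r} (csv, png, svg)")
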