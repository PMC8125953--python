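"""Structure reading, unit selection, and residue reduction.

Every amino acid is reduced to a single *effective atom* — the arithmetic
mean of its heavy-atom coordinates — which is the point at which both the
idealized (T) and observed (O) hydrophobicity distributions are evaluated.
Hydrogens are excluded because most X-ray structures lack them; residues
with missing side-chain atoms are averaged over the atoms present (a
warning is emitted) rather than dropped, so the residue count N, and with
it the uniform reference distribution R = 1/N, is stable.

PDB and mmCIF parsing is delegated to gemmi; only the first model of
multi-model (NMR) entries is used.  Alternate locations are resolved per
atom name to the highest-occupancy copy, first encountered on ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import ConfigurationError, EmptyModelError, FormatError, SelectionError
from .scales import AA_ALIASES, DEFAULT_SCALE, STANDARD_AA, get_scale

#: (chain_id, seq_number, insertion_code) — the stable residue identifier.
ResidueKey = tuple[str, int, str]

_WATER = {"HOH", "WAT", "DOD", "H2O"}

# Heavy-atom counts of complete residues (no OXT), used to warn on
# truncated side chains.
_EXPECTED_HEAVY = {
    "GLY": 4, "ALA": 5, "SER": 6, "CYS": 6, "VAL": 7, "THR": 7, "PRO": 7,
    "ILE": 8, "LEU": 8, "ASN": 8, "ASP": 8, "MET": 8, "GLN": 9, "GLU": 9,
    "LYS": 9, "HIS": 10, "ARG": 11, "PHE": 11, "TYR": 12, "TRP": 14,
}

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass
class ResidueRecord:
    """One amino acid reduced to its effective atom.

    ``atom_coords`` retains the individual heavy-atom positions because
    interface and ligand-pocket detection use any-heavy-atom distances.
    """

    chain_id: str
    seq_number: int
    insertion_code: str
    aa_type: str
    effective_atom: np.ndarray
    intrinsic_hydrophobicity: float | None = None
    atom_coords: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def label(self) -> str:
        icode = self.insertion_code or ""
        return f"{self.chain_id}:{self.seq_number}{icode}:{self.aa_type}"


@dataclass
class StructureModel:
    identifier: str
    residues: list[ResidueRecord]
    hetero_atoms: list[tuple[str, np.ndarray]] = field(default_factory=list)
    secondary_structure: list[tuple[str, str, int, int]] = field(default_factory=list)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def residue_map(self) -> dict[ResidueKey, ResidueRecord]:
        return {r.key: r for r in self.residues}


def effective_atom(atoms) -> np.ndarray:
    """Arithmetic mean of a residue's atom positions."""
    pts = np.asarray(atoms, dtype=float)
    if pts.size == 0:
        raise FormatError("residue has no atoms to average")
    pts = pts.reshape(-1, 3)
    if not np.all(np.isfinite(pts)):
        raise FormatError("non-finite atom coordinate")
    return pts.mean(axis=0)


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Pick one copy per atom name: highest occupancy, first on ties."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def read_structure(
    path: str | Path,
    format: str = "auto",
    include_backbone: bool = True,
) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Standard amino acids (plus common aliases such as MSE) become
    ResidueRecords; non-polymer HETATM entities other than water are kept as
    ``hetero_atoms``; HELIX/SHEET (struct_conf / struct_sheet_range) records
    populate ``secondary_structure``.

    ``include_backbone=False`` restricts the effective atom to side-chain
    heavy atoms (glycine falls back to all heavy atoms); the default uses
    every heavy atom.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise ConfigurationError(f"unknown format {format!r} (pdb, mmcif, auto)")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models")
    model = st[0]

    residues: list[ResidueRecord] = []
    hetero: list[tuple[str, np.ndarray]] = []
    for chain in model:
        for res in chain:
            name = res.name.upper()
            if name in _WATER:
                continue
            aa = name if name in STANDARD_AA else AA_ALIASES.get(name)
            if aa is None:
                for atom in _resolve_altlocs(res):
                    if atom.element.name != "H":
                        hetero.append((name, np.array(atom.pos.tolist())))
                continue
            atoms = [a for a in _resolve_altlocs(res) if a.element.name != "H"]
            if not atoms:
                continue
            coords = np.array([a.pos.tolist() for a in atoms], dtype=float)
            expected = _EXPECTED_HEAVY.get(aa)
            # Single-atom residues are deliberate coarse-grained input
            # (synthetic fixtures carry one effective atom); only warn on
            # partially truncated residues.
            if expected is not None and 1 < len(atoms) < expected:
                warnings.warn(
                    f"{path.name} {chain.name}:{res.seqid.num}{res.seqid.icode.strip()} "
                    f"{name}: {len(atoms)}/{expected} heavy atoms present; "
                    "effective atom averaged over those present",
                    stacklevel=2,
                )
            if include_backbone:
                used = coords
            else:
                side = np.array(
                    [a.pos.tolist() for a in atoms if a.name not in _BACKBONE],
                    dtype=float,
                )
                used = side if len(side) else coords
            residues.append(
                ResidueRecord(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=res.seqid.icode.strip(),
                    aa_type=aa,
                    effective_atom=effective_atom(used),
                    atom_coords=coords,
                )
            )

    if not residues:
        raise EmptyModelError(f"{path}: no standard amino-acid residues")

    secondary: list[tuple[str, str, int, int]] = []
    for helix in st.helices:
        secondary.append(
            ("helix", helix.start.chain_name, helix.start.res_id.seqid.num,
             helix.end.res_id.seqid.num)
        )
    for sheet in st.sheets:
        for strand in sheet.strands:
            secondary.append(
                ("strand", strand.start.chain_name, strand.start.res_id.seqid.num,
                 strand.end.res_id.seqid.num)
            )

    ident = st.name.strip() or path.stem
    return StructureModel(
        identifier=ident,
        residues=residues,
        hetero_atoms=hetero,
        secondary_structure=secondary,
    )


@dataclass(frozen=True)
class UnitSelector:
    """Chain / residue-range selection expression.

    Grammar: terms joined by ``+``; a term is a chain id (``A``) or a chain
    with an author-numbered residue range (``A:272-433``).  Examples:
    ``"A"``, ``"A+C"``, ``"A:272-433"``, ``"A:434-451+B:434-451"``.
    """

    expression: str

    def resolve(self, model: StructureModel) -> list[ResidueRecord]:
        terms = [t.strip() for t in self.expression.split("+") if t.strip()]
        if not terms:
            raise SelectionError(f"empty selector {self.expression!r}")
        selected: dict[ResidueKey, None] = {}
        for term in terms:
            matched = self._match_term(model, term)
            if not matched:
                raise SelectionError(
                    f"selector term {term!r} matched no residues in "
                    f"{model.identifier} (chains: {', '.join(model.chains())})"
                )
            for r in matched:
                selected.setdefault(r.key, None)
        return [r for r in model.residues if r.key in selected]

    @staticmethod
    def _match_term(model: StructureModel, term: str) -> list[ResidueRecord]:
        if ":" in term:
            chain, _, rng = term.partition(":")
            try:
                lo_s, _, hi_s = rng.partition("-")
                lo, hi = int(lo_s), int(hi_s)
            except ValueError as exc:
                raise SelectionError(f"bad range in selector term {term!r}") from exc
            return [
                r for r in model.residues
                if r.chain_id == chain and lo <= r.seq_number <= hi
            ]
        return [r for r in model.residues if r.chain_id == term]


def select_unit(model: StructureModel, selector: UnitSelector | str) -> list[ResidueRecord]:
    """Resolve a selector to an ordered, duplicate-free residue list."""
    if isinstance(selector, str):
        selector = UnitSelector(selector)
    return selector.resolve(model)


def assign_hydrophobicity(
    model: StructureModel,
    scale=DEFAULT_SCALE,
    overrides: dict[ResidueKey, float] | None = None,
) -> StructureModel:
    """Attach intrinsic hydrophobicity from a scale, in place.

    ``overrides`` maps residue keys to explicit values and wins over the
    scale; synthetic fixtures use it to control hydrophobicity independently
    of residue identity.  Returns the model for chaining.
    """
    mapping = get_scale(scale)
    overrides = overrides or {}
    for r in model.residues:
        if r.key in overrides:
            value = float(overrides[r.key])
        elif r.aa_type in mapping:
            value = mapping[r.aa_type]
        else:
            raise ConfigurationError(
                f"residue type {r.aa_type} absent from hydrophobicity scale"
            )
        if not 0.0 <= value <= 1.0:
            raise ConfigurationError(
                f"hydrophobicity {value} for {r.label()} outside [0, 1]"
            )
        r.intrinsic_hydrophobicity = value
    return model


def write_pdb(model: StructureModel, path: str | Path, unit=None) -> Path:
    """Write a minimal PDB file for a model or a selected unit.

    Only ATOM records (plus any hetero atoms) are emitted, at standard PDB
    coordinate precision (3 decimals).  Used for fixtures and round-trip
    tests; not a general-purpose PDB writer.
    """
    path = Path(path)
    residues = unit if unit is not None else model.residues
    lines = []
    serial = 1
    for r in residues:
        coords = r.atom_coords if len(r.atom_coords) else r.effective_atom.reshape(1, 3)
        names = _atom_names(r.aa_type, len(coords))
        for name, xyz in zip(names, coords):
            lines.append(_atom_line(serial, name, r, xyz))
            serial += 1
    for het_name, xyz in (model.hetero_atoms if unit is None else []):
        lines.append(
            f"HETATM{serial:5d}  X   {het_name:<3s}  {9999:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00\n"
        )
        serial += 1
    lines.append("END\n")
    path.write_text("".join(lines))
    return path


def _atom_names(aa: str, n: int) -> list[str]:
    base = ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "CZ", "CH", "CI", "CJ", "CK", "CL"]
    if n == 1:
        return ["CA"]
    return [base[i] if i < len(base) else f"X{i}" for i in range(n)]


def _atom_line(serial: int, name: str, r: ResidueRecord, xyz) -> str:
    padded = f" {name:<3s}" if len(name) < 4 else name
    icode = r.insertion_code or " "
    elem = name[1] if name[0].isdigit() else name[0]
    return (
        f"ATOM  {serial:5d} {padded}{'':1s}{r.aa_type:<3s} {r.chain_id:1s}"
        f"{r.seq_number:4d}{icode:1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {elem:>2s}\n"
    )


def write_hydrophobicity_sidecar(model: StructureModel, path: str | Path) -> Path:
    """Write per-residue hydrophobicity overrides as TSV (chain, seq, icode, H)."""
    path = Path(path)
    rows = ["chain\tseq\ticode\thydrophobicity\n"]
    for r in model.residues:
        if r.intrinsic_hydrophobicity is None:
            raise ConfigurationError("model has unassigned hydrophobicity")
        rows.append(
            f"{r.chain_id}\t{r.seq_number}\t{r.insertion_code}\t"
            f"{r.intrinsic_hydrophobicity:.17g}\n"
        )
    path.write_text("".join(rows))
    return path


def read_hydrophobicity_sidecar(path: str | Path) -> dict[ResidueKey, float]:
    """Read a TSV override file written by :func:`write_hydrophobicity_sidecar`."""
    overrides: dict[ResidueKey, float] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        chain, seq, icode, value = line.split("\t")
        overrides[(chain, int(seq), icode)] = float(value)
    return overrides
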