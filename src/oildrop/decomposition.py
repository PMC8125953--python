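"""Unit decomposition: interfaces, ligand pockets, restricted RD, elimination.

A complex that scores RD > 0.5 as a whole often hides an accordant part:
the mismatching residues are typically those engaged in inter-chain
contacts or ligand binding.  This module finds those residue sets by
heavy-atom distance criteria, scores arbitrary subsets with a *restricted*
RD (the full unit's raw T and O values cut down to the subset and
renormalized, so the subset is judged inside the geometry it actually
occupies), and runs a greedy elimination that strips the worst-deviating
residues until the remainder scores below the hydrophobic-core threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, SelectionError
from .fod_core import (
    DEFAULT_CUTOFF,
    EnvelopeSource,
    FODResult,
    fod_result,
    hydro_profile,
    rd_score,
)
from .structure_io import ResidueKey, ResidueRecord, StructureModel, select_unit

#: Default any-heavy-atom contact cutoff for interfaces and pockets, in Å.
DEFAULT_CONTACT_CUTOFF = 5.0

#: Core-order threshold on RD.
RD_THRESHOLD = 0.5


@dataclass
class ResidueSubsetStatus:
    label: str
    members: frozenset[ResidueKey]
    result: FODResult


@dataclass
class EliminationTrace:
    order: list[tuple[ResidueKey, float]] = field(default_factory=list)
    rd_path: list[float] = field(default_factory=list)
    final_subset: frozenset[ResidueKey] = frozenset()
    reached_threshold: bool = False

    @property
    def removed(self) -> list[ResidueKey]:
        return [key for key, _ in self.order]


def _atom_table(unit: Sequence[ResidueRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack heavy-atom coordinates with a residue-index column."""
    coords, owner = [], []
    for i, r in enumerate(unit):
        pts = r.atom_coords if len(r.atom_coords) else r.effective_atom.reshape(1, 3)
        coords.append(pts)
        owner.append(np.full(len(pts), i))
    return np.vstack(coords), np.concatenate(owner)


def interface_residues(
    model: StructureModel,
    unit_a,
    unit_b,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> frozenset[ResidueKey]:
    """Residues of unit_a with any heavy atom within the cutoff of unit_b.

    The criterion is symmetric at the atom-pair level; call with the units
    swapped for the other side of the interface.
    """
    res_a = select_unit(model, unit_a) if not _is_unit(unit_a) else list(unit_a)
    res_b = select_unit(model, unit_b) if not _is_unit(unit_b) else list(unit_b)
    keys_a = {r.key for r in res_a}
    if keys_a & {r.key for r in res_b}:
        raise SelectionError("interface units overlap")
    coords_a, owner_a = _atom_table(res_a)
    coords_b, _ = _atom_table(res_b)
    tree = cKDTree(coords_b)
    hits = tree.query_ball_point(coords_a, r=contact_cutoff)
    touched = {owner_a[i] for i, lst in enumerate(hits) if lst}
    return frozenset(res_a[i].key for i in touched)


def ligand_binding_residues(
    model: StructureModel,
    ligand_name: str,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    unit=None,
) -> frozenset[ResidueKey]:
    """Residues with any heavy atom within the cutoff of the named ligand."""
    ligand_name = ligand_name.upper()
    lig = np.array(
        [xyz for name, xyz in model.hetero_atoms if name.upper() == ligand_name]
    )
    if lig.size == 0:
        available = sorted({name for name, _ in model.hetero_atoms})
        raise SelectionError(
            f"no hetero entity {ligand_name!r} in {model.identifier}; "
            f"available: {available or 'none'}"
        )
    residues = list(unit) if unit is not None else model.residues
    coords, owner = _atom_table(residues)
    tree = cKDTree(lig.reshape(-1, 3))
    hits = tree.query_ball_point(coords, r=contact_cutoff)
    touched = {owner[i] for i, lst in enumerate(hits) if lst}
    return frozenset(residues[i].key for i in touched)


def _is_unit(obj) -> bool:
    return isinstance(obj, (list, tuple)) and (not obj or isinstance(obj[0], ResidueRecord))


def restricted_rd(
    unit: Sequence[ResidueRecord],
    subset: Iterable[ResidueKey],
    envelope_source: EnvelopeSource = "self",
    parent_unit: Sequence[ResidueRecord] | None = None,
    cutoff_c: float = DEFAULT_CUTOFF,
) -> FODResult:
    """RD of a residue subset judged within the full unit's geometry.

    T and O are computed over the envelope-source geometry (the unit, or
    its parent assembly), restricted to the subset, and renormalized;
    R = 1/|subset|.  With the subset equal to the whole unit this is
    exactly ``rd_score``.
    """
    subset = set(subset)
    members = [r for r in unit if r.key in subset]
    if len(members) < 2:
        raise ConfigurationError(
            f"restricted subset has {len(members)} residues; need at least 2"
        )
    source = parent_unit if envelope_source == "parent" else list(unit)
    profile = hydro_profile(
        members, envelope_source="parent", parent_unit=source, cutoff_c=cutoff_c,
    )
    return profile.result()


def complement_status(
    unit: Sequence[ResidueRecord],
    subset: Iterable[ResidueKey],
    labels: tuple[str, str],
    envelope_source: EnvelopeSource = "self",
    parent_unit: Sequence[ResidueRecord] | None = None,
    cutoff_c: float = DEFAULT_CUTOFF,
) -> tuple[ResidueSubsetStatus, ResidueSubsetStatus]:
    """Score a subset and its complement (e.g. "P-P" vs "No P-P")."""
    subset = frozenset(subset)
    rest = frozenset(r.key for r in unit) - subset
    pos = ResidueSubsetStatus(
        labels[0], subset,
        restricted_rd(unit, subset, envelope_source, parent_unit, cutoff_c),
    )
    neg = ResidueSubsetStatus(
        labels[1], rest,
        restricted_rd(unit, rest, envelope_source, parent_unit, cutoff_c),
    )
    return pos, neg


def greedy_elimination(
    unit: Sequence[ResidueRecord],
    threshold: float = RD_THRESHOLD,
    envelope_source: EnvelopeSource = "self",
    parent_unit: Sequence[ResidueRecord] | None = None,
    cutoff_c: float = DEFAULT_CUTOFF,
    adaptive: bool = True,
) -> EliminationTrace:
    """Strip worst-deviating residues until the remainder scores RD < threshold.

    At each step the residue with the largest |O_i - T_i| (on the
    renormalized remaining subset) is removed and the restricted RD
    recomputed; ties break to the lowest residue index.  Stops when RD
    drops below the threshold or fewer than 3 residues would remain.  With
    ``adaptive=False`` the removal order is fixed by the initial deviations
    instead of being recomputed each step.
    """
    if len(unit) < 3:
        raise ConfigurationError("greedy elimination needs at least 3 residues")
    profile = hydro_profile(
        unit, envelope_source=envelope_source, parent_unit=parent_unit,
        cutoff_c=cutoff_c,
    )
    # Raw (unnormalized) values over the full unit; subsets renormalize.
    t_raw = profile.T.copy()
    o_raw = profile.O.copy()
    keys = [r.key for r in unit]

    remaining = list(range(len(unit)))
    trace = EliminationTrace()

    def _restricted(idx: list[int]) -> tuple[np.ndarray, np.ndarray, FODResult]:
        t = t_raw[idx] / t_raw[idx].sum()
        o_total = o_raw[idx].sum()
        n = len(idx)
        o = o_raw[idx] / o_total if o_total > 0 else np.full(n, 1.0 / n)
        r = np.full(n, 1.0 / n)
        return t, o, fod_result(o, t, r)

    t, o, res = _restricted(remaining)
    initial_dev = np.abs(o - t)
    rd = res.rd
    while rd >= threshold and len(remaining) > 3:
        if adaptive:
            dev = np.abs(o - t)
        else:
            dev = initial_dev[remaining]
        worst = int(np.argmax(dev))  # argmax returns the first (lowest-index) max
        key = keys[remaining[worst]]
        trace.order.append((key, float(dev[worst])))
        del remaining[worst]
        t, o, res = _restricted(remaining)
        rd = res.rd
        trace.rd_path.append(rd)

    trace.final_subset = frozenset(keys[i] for i in remaining)
    trace.reached_threshold = rd < threshold
    return trace


def fragment_status(
    model: StructureModel,
    unit,
    fragments,
    envelope_source: EnvelopeSource = "self",
    parent_unit: Sequence[ResidueRecord] | None = None,
    cutoff_c: float = DEFAULT_CUTOFF,
) -> list[ResidueSubsetStatus]:
    """Score secondary-structure classes or custom ranges within a unit.

    ``fragments`` is either a keyword — ``"helix"`` / ``"strand"``, which
    pools every residue of that class from the model's secondary-structure
    records falling inside the unit — or a mapping of label to a list of
    ``(chain_id, start, end)`` author-numbered ranges.
    """
    residues = select_unit(model, unit) if not _is_unit(unit) else list(unit)
    unit_keys = {r.key for r in residues}

    def _keys_for_ranges(ranges) -> frozenset[ResidueKey]:
        keys = set()
        for chain_id, start, end in ranges:
            keys.update(
                r.key for r in residues
                if r.chain_id == chain_id and start <= r.seq_number <= end
            )
        return frozenset(keys)

    classes: dict[str, frozenset[ResidueKey]] = {}
    if isinstance(fragments, str):
        wanted = {"helix": "helix", "strand": "strand", "beta": "strand"}[fragments.lower()]
        ranges = [
            (chain, start, end)
            for kind, chain, start, end in model.secondary_structure
            if kind == wanted
        ]
        classes[fragments] = _keys_for_ranges(ranges)
    else:
        for label, ranges in fragments.items():
            classes[label] = _keys_for_ranges(ranges)

    statuses = []
    for label, keys in classes.items():
        if not keys:
            raise SelectionError(f"fragment class {label!r} matched no residues")
        if not keys <= unit_keys:
            raise SelectionError(f"fragment class {label!r} extends outside the unit")
        result = restricted_rd(
            residues, keys, envelope_source=envelope_source,
            parent_unit=parent_unit, cutoff_c=cutoff_c,
        )
        statuses.append(ResidueSubsetStatus(label, keys, result))
    return statuses
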