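"""The fuzzy-oil-drop core: T, O, R distributions and the RD statistic.

The model idealizes a soluble globular protein as a "fuzzy oil drop": a 3D
Gaussian hydrophobicity density, maximal at the molecular center and close
to zero at the surface.  Three per-residue distributions are compared, each
normalized to sum 1 over the N residues of the analyzed unit:

* **T** (theoretical) — the Gaussian evaluated at each effective atom, in
  the unit's principal frame, with per-axis widths ``sigma`` calibrated to
  the molecule's extent;
* **O** (observed) — hydrophobicity collected from pairwise inter-residue
  interactions: each pair within a cutoff ``c`` contributes
  ``(H_i + H_j) * w(r_ij / c)``, where ``H`` is intrinsic hydrophobicity
  and ``w`` a smooth polynomial contact weight that decays from 1 at
  contact to 0 at the cutoff;
* **R** (uniform) — 1/N everywhere, i.e. no core at all.

Divergence-of-entropy distances D_KL(O‖T) and D_KL(O‖R) (in bits) are
combined into the relative distance

    RD = D_KL(O‖T) / (D_KL(O‖T) + D_KL(O‖R)),

so RD < 0.5 means O sits closer to the idealized core than to featureless
uniformity — the unit has a hydrophobic core and a polar surface.

Two envelope sources are supported: ``self`` refits the Gaussian on the
analyzed unit (the unit as an individual molecule), while ``parent``
evaluates the Gaussian and the pairwise interactions of an enclosing
assembly at the unit's residues and renormalizes over the unit — the status
of a chain *inside* its complex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence
import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigurationError, DegenerateGeometryError
from .structure_io import ResidueRecord

#: Default interaction cutoff for the observed distribution, in Å.
DEFAULT_CUTOFF = 9.0

#: Floor for Gaussian axis widths, in Å (guards near-planar/linear units).
SIGMA_FLOOR = 1.0

EnvelopeSource = Literal["self", "parent"]


@dataclass(frozen=True)
class GaussianEnvelope:
    """The fitted 3D Gaussian: center, per-axis sigma, principal-frame rotation."""

    center: np.ndarray
    sigma: np.ndarray
    rotation: np.ndarray  # rows are principal axes; local = R @ (x - center)

    def to_local(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, dtype=float) - self.center) @ self.rotation.T

    def density(self, coords: np.ndarray) -> np.ndarray:
        """Unnormalized Gaussian value at each coordinate."""
        local = self.to_local(coords)
        return np.exp(-0.5 * np.sum((local / self.sigma) ** 2, axis=1))


@dataclass(frozen=True)
class FODResult:
    dkl_OT: float
    dkl_OR: float
    rd: float
    n_residues: int


@dataclass(frozen=True)
class HydroProfile:
    unit: tuple
    T: np.ndarray
    O: np.ndarray
    R: np.ndarray
    envelope: GaussianEnvelope
    cutoff_c: float
    scale_name: str = ""

    def result(self) -> FODResult:
        return fod_result(self.O, self.T, self.R)


def _coords(unit: Sequence) -> np.ndarray:
    if len(unit) and isinstance(unit[0], ResidueRecord):
        return np.array([r.effective_atom for r in unit], dtype=float)
    return np.asarray(unit, dtype=float)


def _hydrophobicities(unit: Sequence[ResidueRecord]) -> np.ndarray:
    values = []
    for r in unit:
        if r.intrinsic_hydrophobicity is None:
            raise ConfigurationError(
                f"residue {r.label()} has no intrinsic hydrophobicity assigned"
            )
        values.append(r.intrinsic_hydrophobicity)
    return np.asarray(values, dtype=float)


def orient_and_fit(unit: Sequence, sigma_floor: float = SIGMA_FLOOR) -> GaussianEnvelope:
    """Fit the Gaussian envelope to a unit's effective atoms.

    The cloud is centered on its mean and rotated into the principal axes
    of its covariance (largest variance along x).  Each axis width is the
    maximum absolute coordinate along that axis divided by 3, so the
    molecule sits within 3 sigma of the center; widths are floored at
    ``sigma_floor`` Å.
    """
    coords = _coords(unit)
    if len(coords) < 2:
        raise DegenerateGeometryError("need at least 2 residues to fit an envelope")
    center = coords.mean(axis=0)
    centered = coords - center
    cov = centered.T @ centered / len(centered)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[-1] <= 1e-12:
        raise DegenerateGeometryError("all effective atoms coincide")
    order = np.argsort(eigvals)[::-1]
    rotation = eigvecs[:, order].T
    if np.linalg.det(rotation) < 0:
        rotation = rotation.copy()
        rotation[2] *= -1.0
    local = centered @ rotation.T
    sigma = np.maximum(np.abs(local).max(axis=0) / 3.0, sigma_floor)
    return GaussianEnvelope(center=center, sigma=sigma, rotation=rotation)


def t_distribution(unit: Sequence, envelope: GaussianEnvelope) -> np.ndarray:
    """Normalized Gaussian density at the unit's effective atoms."""
    raw = envelope.density(_coords(unit))
    return raw / raw.sum()


def contact_weight(t) -> np.ndarray:
    """Smooth contact weight on the scaled distance t = r/c.

    w(0) = 1, w(1) = 0, with zero slope at both ends; w = 0 beyond the
    cutoff.  This is the even-polynomial soft-sphere weight used throughout
    the fuzzy-oil-drop literature for hydrophobic interaction strength.
    """
    t = np.asarray(t, dtype=float)
    t2 = t * t
    w = 1.0 - 0.5 * (7.0 * t2 - 9.0 * t2**2 + 5.0 * t2**3 - t2**4)
    return np.where(t <= 1.0, w, 0.0)


def raw_o(
    coords: np.ndarray, hydrophobicity: np.ndarray, cutoff: float = DEFAULT_CUTOFF
) -> np.ndarray:
    """Unnormalized observed hydrophobicity collected at each residue.

    O~_i = sum over j != i within the cutoff of (H_i + H_j) * w(r_ij / c).
    No self-term: a residue only collects from its interaction partners.
    """
    if cutoff <= 0:
        raise ConfigurationError(f"interaction cutoff must be positive, got {cutoff}")
    n = len(coords)
    if n == 1:
        return np.ones(1)
    dist = squareform(pdist(coords))
    with np.errstate(invalid="ignore"):
        w = contact_weight(dist / cutoff)
    np.fill_diagonal(w, 0.0)
    h = np.asarray(hydrophobicity, dtype=float)
    # sum_j (H_i + H_j) w_ij = H_i * sum_j w_ij + sum_j H_j w_ij
    return h * w.sum(axis=1) + w @ h


def o_distribution(
    unit: Sequence[ResidueRecord], cutoff_c: float = DEFAULT_CUTOFF
) -> np.ndarray:
    """Normalized observed distribution over a unit."""
    raw = raw_o(_coords(unit), _hydrophobicities(unit), cutoff_c)
    total = raw.sum()
    if total <= 0.0:
        warnings.warn(
            "no residue pair within the interaction cutoff; "
            "observed distribution falls back to uniform",
            stacklevel=2,
        )
        return np.full(len(raw), 1.0 / len(raw))
    return raw / total


def kl_divergence(p, q, base: float = 2.0) -> float:
    """D_KL(p ‖ q) = sum p_i log(p_i / q_i), with 0 log 0 = 0.

    Reported in bits by default; RD itself is base-invariant.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0.0
    if np.any(q[mask] <= 0.0):
        raise ConfigurationError("undefined divergence: p > 0 where q = 0")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])) / np.log(base))


def fod_result(O, T, R) -> FODResult:
    """Combine distributions into D_KL distances and the RD statistic.

    When O matches both references exactly (both divergences zero, possible
    only for degenerate units where T is itself uniform), RD is defined as
    0: the unit is trivially accordant with the idealized core.
    """
    dkl_ot = kl_divergence(O, T)
    dkl_or = kl_divergence(O, R)
    denom = dkl_ot + dkl_or
    rd = dkl_ot / denom if denom > 0.0 else 0.0
    return FODResult(dkl_OT=dkl_ot, dkl_OR=dkl_or, rd=rd, n_residues=len(np.asarray(O)))


def _subset_indices(source: Sequence[ResidueRecord], unit: Sequence[ResidueRecord]) -> np.ndarray:
    pos = {r.key: i for i, r in enumerate(source)}
    try:
        return np.array([pos[r.key] for r in unit], dtype=int)
    except KeyError as exc:
        raise ConfigurationError(
            f"unit residue {exc.args[0]} not contained in the parent unit"
        ) from exc


def hydro_profile(
    unit: Sequence[ResidueRecord],
    envelope_source: EnvelopeSource = "self",
    parent_unit: Sequence[ResidueRecord] | None = None,
    cutoff_c: float = DEFAULT_CUTOFF,
    sigma_floor: float = SIGMA_FLOOR,
    scale_name: str = "",
) -> HydroProfile:
    """Build the T/O/R profile of a unit.

    ``envelope_source="self"`` fits the Gaussian on the unit and collects
    interactions within the unit only.  ``envelope_source="parent"``
    computes both the Gaussian and the pairwise interactions on
    ``parent_unit`` (which must contain the unit), restricts the raw values
    to the unit's residues, and renormalizes — the unit's status as part of
    the larger assembly.
    """
    if len(unit) < 1:
        raise ConfigurationError("empty unit")
    if len(unit) == 1 and (envelope_source == "self" or parent_unit is None):
        # a lone residue: every normalized distribution is trivially [1]
        one = np.ones(1)
        env = GaussianEnvelope(
            center=_coords(unit)[0],
            sigma=np.full(3, sigma_floor),
            rotation=np.eye(3),
        )
        return HydroProfile(unit=tuple(unit), T=one, O=one.copy(), R=one.copy(),
                            envelope=env, cutoff_c=cutoff_c, scale_name=scale_name)
    if envelope_source == "self":
        source = unit
    elif envelope_source == "parent":
        if parent_unit is None:
            raise ConfigurationError("envelope_source='parent' requires parent_unit")
        source = parent_unit
    else:
        raise ConfigurationError(f"unknown envelope source {envelope_source!r}")

    envelope = orient_and_fit(source, sigma_floor=sigma_floor)
    src_coords = _coords(source)
    raw_t_all = envelope.density(src_coords)
    raw_o_all = raw_o(src_coords, _hydrophobicities(source), cutoff_c)

    idx = _subset_indices(source, unit) if source is not unit else np.arange(len(unit))
    t_raw = raw_t_all[idx]
    o_raw = raw_o_all[idx]

    T = t_raw / t_raw.sum()
    o_total = o_raw.sum()
    n = len(idx)
    if o_total <= 0.0:
        warnings.warn(
            "no residue pair within the interaction cutoff; "
            "observed distribution falls back to uniform",
            stacklevel=2,
        )
        O = np.full(n, 1.0 / n)
    else:
        O = o_raw / o_total
    R = np.full(n, 1.0 / n)
    return HydroProfile(
        unit=tuple(unit), T=T, O=O, R=R,
        envelope=envelope, cutoff_c=cutoff_c, scale_name=scale_name,
    )


def rd_score(
    unit: Sequence[ResidueRecord],
    envelope_source: EnvelopeSource = "self",
    parent_unit: Sequence[ResidueRecord] | None = None,
    cutoff_c: float = DEFAULT_CUTOFF,
    sigma_floor: float = SIGMA_FLOOR,
) -> FODResult:
    """RD of a unit under the chosen envelope source."""
    if len(unit) < 2:
        raise ConfigurationError("rd_score needs a unit of at least 2 residues")
    profile = hydro_profile(
        unit, envelope_source=envelope_source, parent_unit=parent_unit,
        cutoff_c=cutoff_c, sigma_floor=sigma_floor,
    )
    return profile.result()
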