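"""Synthetic structure generator with controlled hydrophobicity geometry.

Real globular proteins bury hydrophobic residues and expose polar ones; the
generator reproduces that organization (and its pathologies) directly, so
every pipeline stage can be exercised without touching a structure
database:

* ``micelle`` — residues packed on concentric shells, intrinsic
  hydrophobicity decreasing from the center outwards: a soluble,
  core-ordered globule (RD < 0.5 by construction);
* ``inverted_micelle`` — the reverse gradient: hydrophobic surface, polar
  interior, the membrane-compatible / aggregation-prone regime (RD > 0.5);
* ``uniform`` — identical hydrophobicity everywhere;
* ``two_domain`` — two micelle globules joined by a sparse extended
  linker: each domain is core-ordered on its own while the whole chain is
  not, the signature of multi-domain chains;
* ``fibril_stack`` — one globule repeated along an axis as separate
  chains: an elongated non-globular assembly;
* ``planted_outliers`` — a moderately ordered micelle plus a few surface
  residues forced to maximal hydrophobicity: known ground truth for the
  greedy-elimination procedure.

Residues are written as single-effective-atom alanines; hydrophobicity is
carried by a sidecar override table rather than by residue identity, so
fixtures stay standard-PDB-parseable while hydrophobicity is controlled
exactly.  Placement is seeded rejection sampling with a hard spacing floor;
nothing about the geometry is physically folded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GenerationError
from .structure_io import (
    ResidueRecord,
    StructureModel,
    write_hydrophobicity_sidecar,
    write_pdb,
)

#: Minimum inter-residue (effective-atom) spacing, in Å — roughly the
#: closest approach of residue centroids in packed proteins.
MIN_SPACING = 3.5

REGIMES = (
    "micelle", "inverted_micelle", "uniform", "two_domain",
    "fibril_stack", "planted_outliers",
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic structure.

    ``contrast`` in [0, 1] sets the strength of the radial hydrophobicity
    gradient: 0 is flat at 0.5, 1 spans the full [0, 1] range from core to
    surface.  ``outlier_count`` applies to the planted_outliers regime
    only; its base globule is hollowed and slightly softened so the planted
    surface-hydrophobic patch dominates the T/O mismatch.
    """

    regime: str = "micelle"
    n_residues: int = 60
    radius: float = 18.0
    seed: int = 0
    contrast: float = 1.0
    outlier_count: int = 3
    n_globules: int = 4  # fibril_stack only
    linker_fraction: float = 0.1  # two_domain only

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise GenerationError(f"unknown regime {self.regime!r}; one of {REGIMES}")
        if self.n_residues < 3:
            raise GenerationError("n_residues must be at least 3")
        if self.radius <= 0:
            raise GenerationError("radius must be positive")
        if not 0.0 <= self.contrast <= 1.0:
            raise GenerationError("contrast must lie in [0, 1]")


def _pack_ball(
    rng: np.random.Generator, n: int, radius: float, center: np.ndarray
) -> np.ndarray:
    """Rejection-sample n points uniformly in a ball with the spacing floor."""
    points: list[np.ndarray] = []
    attempts = 0
    max_attempts = 4000 * n
    while len(points) < n:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"cannot pack {n} residues at {MIN_SPACING} Å spacing into a "
                f"ball of radius {radius} Å; increase the radius"
            )
        p = rng.uniform(-radius, radius, size=3)
        if p @ p > radius * radius:
            continue
        if points and np.min(np.linalg.norm(np.array(points) - p, axis=1)) < MIN_SPACING:
            continue
        points.append(p)
    return np.array(points) + center


def _pack_shells(
    rng: np.random.Generator,
    n: int,
    radius: float,
    center: np.ndarray,
    inner_fraction: float | None = None,
) -> np.ndarray:
    """Place n points on concentric spherical shells with the spacing floor.

    Shell radii step by roughly the spacing floor; per-shell counts scale
    with shell area, so packing density is near-uniform through the volume
    — the layered, globule-like arrangement the micelle regimes emulate.
    ``inner_fraction`` sets the innermost shell radius as a fraction of the
    outer radius (default: one spacing step).
    """
    if inner_fraction is None:
        n_shells = max(2, int(radius / MIN_SPACING))
        inner = radius / n_shells
    else:
        inner = inner_fraction * radius
        n_shells = max(2, int((radius - inner) / MIN_SPACING) + 1)
    radii = np.linspace(inner, radius, n_shells)
    weights = radii**2
    counts = np.maximum(1, np.round(n * weights / weights.sum()).astype(int))
    while counts.sum() > n:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n:
        counts[-1] += 1
    points: list[np.ndarray] = []
    for r, c in zip(radii, counts):
        placed = 0
        attempts = 0
        while placed < c:
            attempts += 1
            if attempts > 4000 * c:
                raise GenerationError(
                    f"cannot place {c} residues on a shell of radius {r:.1f} Å "
                    f"at {MIN_SPACING} Å spacing; increase the radius"
                )
            v = rng.normal(size=3)
            p = r * v / np.linalg.norm(v)
            if points and np.min(np.linalg.norm(np.array(points) - p, axis=1)) < MIN_SPACING:
                continue
            points.append(p)
            placed += 1
    return np.array(points) + center


def _radial_hydro(coords: np.ndarray, center: np.ndarray, radius: float,
                  contrast: float, inverted: bool = False) -> np.ndarray:
    """Gaussian-shaped radial hydrophobicity decay (or its inversion).

    The idealized micelle is the 3D Gaussian with sigma about one third of
    the molecular extent, so a perfectly ordered globule carries intrinsic
    hydrophobicity following exp(-4.5 (r/R)^2): near 1 at the core, near 0
    at the surface.  ``contrast`` interpolates between that profile and a
    flat 0.5.
    """
    r = np.linalg.norm(coords - center, axis=1)
    gradient = np.exp(-4.5 * (r / radius) ** 2)
    if inverted:
        gradient = 1.0 - gradient
    return 0.5 * (1.0 - contrast) + contrast * gradient


def _records(coords: np.ndarray, hydro: np.ndarray, chain_id: str = "A",
             start: int = 1) -> list[ResidueRecord]:
    return [
        ResidueRecord(
            chain_id=chain_id,
            seq_number=start + i,
            insertion_code="",
            aa_type="ALA",
            effective_atom=np.round(xyz, 3),  # PDB coordinate precision
            intrinsic_hydrophobicity=float(h),
            atom_coords=np.round(xyz, 3).reshape(1, 3),
        )
        for i, (xyz, h) in enumerate(zip(coords, hydro))
    ]


def generate(spec: GeneratorSpec) -> StructureModel:
    """Build a StructureModel for the given generator spec (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    n, radius, kappa = spec.n_residues, spec.radius, spec.contrast
    origin = np.zeros(3)

    if spec.regime in ("micelle", "inverted_micelle", "uniform"):
        if spec.regime == "uniform":
            coords = _pack_ball(rng, n, radius, origin)
            hydro = np.full(n, 0.5)
        else:
            coords = _pack_shells(rng, n, radius, origin)
            hydro = _radial_hydro(
                coords, origin, radius, kappa,
                inverted=spec.regime == "inverted_micelle",
            )
        residues = _records(coords, hydro)

    elif spec.regime == "planted_outliers":
        k = spec.outlier_count
        if k >= n:
            raise GenerationError("outlier_count must be smaller than n_residues")
        # Base globule: hollow-core shells (no residue sits at the Gaussian
        # peak, where the observed distribution could never follow) with a
        # slightly softened gradient, so the whole-unit mismatch is carried
        # by the planted patch rather than by packing noise.
        coords = _pack_shells(rng, n - k, radius, origin, inner_fraction=0.55)
        hydro = _radial_hydro(coords, origin, radius, kappa * 0.9)
        # The outliers form a tight hydrophobic protrusion just above the
        # surface: mutually within interaction range (so each keeps the
        # others' observed excess high until all are removed) but too far
        # from the globule to inflate its residues.  Numbered after the
        # globule so ground truth is recoverable from seq_number.
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        shell: list[np.ndarray] = [1.3 * radius * axis]
        while len(shell) < k:
            v = axis + 0.10 * rng.normal(size=3)
            p = 1.3 * radius * v / np.linalg.norm(v)
            taken = np.vstack([coords, np.array(shell)])
            if np.min(np.linalg.norm(taken - p, axis=1)) < MIN_SPACING:
                continue
            if np.min(np.linalg.norm(np.array(shell) - p, axis=1)) > 4.5:
                continue
            shell.append(p)
        coords = np.vstack([coords, shell])
        hydro = np.concatenate([hydro, np.ones(k)])
        residues = _records(coords, hydro)

    elif spec.regime == "two_domain":
        n_link = max(3, int(round(spec.linker_fraction * n)))
        n_dom = (n - n_link) // 2
        n_dom2 = n - n_link - n_dom
        gap = 3.0 * radius
        c1 = np.array([-(radius + gap / 2), 0.0, 0.0])
        c2 = np.array([+(radius + gap / 2), 0.0, 0.0])
        d1 = _pack_shells(rng, n_dom, radius, c1)
        d2 = _pack_shells(rng, n_dom2, radius, c2)
        # Extended linker: evenly spaced along the inter-domain axis with
        # small lateral jitter — low density, no core of its own.
        xs = np.linspace(c1[0] + radius, c2[0] - radius, n_link)
        link = np.column_stack(
            [xs, rng.normal(0, 1.0, n_link), rng.normal(0, 1.0, n_link)]
        )
        h1 = _radial_hydro(d1, c1, radius, kappa)
        h2 = _radial_hydro(d2, c2, radius, kappa)
        hl = np.full(n_link, 0.2)  # polar, exposed linker
        coords = np.vstack([d1, link, d2])
        hydro = np.concatenate([h1, hl, h2])
        residues = _records(coords, hydro)

    elif spec.regime == "fibril_stack":
        m = spec.n_globules
        per = n  # n residues per globule, repeated as separate chains
        template = _pack_shells(rng, per, radius, origin)
        h = _radial_hydro(template, origin, radius, kappa)
        residues = []
        for g in range(m):
            offset = np.array([0.0, 0.0, g * 2.05 * radius])
            chain_id = chr(ord("A") + g)
            residues.extend(_records(template + offset, h, chain_id=chain_id))
    else:  # pragma: no cover - guarded by GeneratorSpec
        raise GenerationError(spec.regime)

    return StructureModel(identifier=f"synthetic-{spec.regime}-{spec.seed}",
                          residues=residues)


def domain_selectors(spec: GeneratorSpec) -> tuple[str, str]:
    """Author-numbered selectors for the two domains of a two_domain model."""
    if spec.regime != "two_domain":
        raise GenerationError("domain_selectors applies to the two_domain regime")
    n = spec.n_residues
    n_link = max(3, int(round(spec.linker_fraction * n)))
    n_dom = (n - n_link) // 2
    return (f"A:1-{n_dom}", f"A:{n_dom + n_link + 1}-{n}")


def outlier_keys(spec: GeneratorSpec) -> frozenset:
    """Ground-truth residue keys of the planted outliers."""
    if spec.regime != "planted_outliers":
        raise GenerationError("outlier_keys applies to the planted_outliers regime")
    n, k = spec.n_residues, spec.outlier_count
    return frozenset(("A", i, "") for i in range(n - k + 1, n + 1))


def write_fixture(model: StructureModel, path: str | Path) -> tuple[Path, Path]:
    """Write a model as minimal PDB plus a hydrophobicity sidecar.

    The sidecar (``<path>.hyd``) records every residue's generated
    hydrophobicity; reading the PDB back and applying the sidecar as
    overrides reproduces the model exactly (coordinates are already stored
    at PDB precision, so the round trip is lossless).
    """
    path = Path(path)
    pdb_path = write_pdb(model, path)
    sidecar = write_hydrophobicity_sidecar(model, path.with_suffix(path.suffix + ".hyd"))
    return pdb_path, sidecar
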