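"""Synthetic study data: disc phantoms, count matrices, eclosion tables.

Every downstream stage of the pipeline (voxel classification, volumetry,
pH3 counting, signature clustering, cohort statistics) is exercised on data
from this module, so each generator is a pure function of ``(params, seed)``
and ships its ground truth alongside the rendered data.

Disc phantoms
-------------
A phantom mimics a confocal stack of an eye-antennal imaginal disc carrying
GFP-labelled mutant clones: the tissue is the union of two overlapping
ellipsoidal lobes ("eye" and "antennal"), clones are smooth random blobs
grown inside the tissue until they occupy a configured fraction of the
tissue volume, and three channels are rendered (DAPI = tissue with nuclear
texture, GFP = clone support, pH3 = Gaussian spots placed at
compartment-specific Poisson densities). Noise is Poisson shot noise plus
Gaussian read noise, controlled by a single ``snr`` parameter.

Condition presets carry the published mean tumor-volume fractions for each
genotype (e.g. 46% for ph505 clones, 5% after kni knock-down in the same
background) so parameter-recovery experiments can be run against known
targets. The phantoms are deliberately desk-scale: a real disc is of order
1e6–1e7 um^3 while a default phantom tissue is ~1e4 um^3; pH3 densities are
scaled accordingly (see docs/methods.md).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ImageStack
from .stats import EclosionRecord

__all__ = [
    "DiscPhantomParams",
    "GroundTruth",
    "CountSimParams",
    "EclosionSimParams",
    "VOLUME_PRESETS",
    "ECLOSION_PRESETS",
    "make_condition_preset",
    "make_eclosion_preset",
    "simulate_disc",
    "simulate_expression",
    "simulate_eclosion",
    "ground_truth_labels",
]

UM3_PER_MM3 = 1e9

#: Published mean tumor-volume fraction per condition (proportion of the
#: DAPI tissue volume occupied by GFP+ clones). FRT19A neutral clones have
#: no printed fraction; 0.25 is a declared stand-in.
VOLUME_PRESETS: dict[str, float] = {
    "FRT19A": 0.25,
    "ph505": 0.46,
    "ph505_rescue": 0.07,
    "ph505_cadKD": 0.14,
    "ph505_drmKD": 0.13,
    "ph505_kniKD": 0.05,
    "ph505_kniKD2": 0.14,
    "ph505_bgcnKD": 0.14,
    "ph505_kniKD_p35": 0.06,
    "ph505_ato": 0.03,
}

#: Published eclosion probabilities (adults / selected larvae).
ECLOSION_PRESETS: dict[str, float] = {
    "FRT19A": 0.99,
    "ph505": 0.12,
    "ph505_rescue": 0.97,
    "ph505_ato": 0.84,
    "ph505_kniKD2": 0.85,
    "kni_ectopic": 0.35,
    "ph505_dome": 0.85,
}


@dataclass(frozen=True)
class DiscPhantomParams:
    """Geometry, content and noise settings for one disc phantom.

    ``voxel_size_um`` defaults to 1.0 x 0.5 x 0.5 um (z, y, x): ~1 um optical
    sectioning with typical 20-40x confocal in-plane sampling.
    """

    target_clone_fraction: float
    shape_voxels: tuple[int, int, int] = (24, 80, 80)
    voxel_size_um: tuple[float, float, float] = (1.0, 0.5, 0.5)
    n_clones_range: tuple[int, int] = (2, 5)
    ph3_density_inside_per_mm3: float = 3.0e6
    ph3_density_outside_per_mm3: float = 1.2e6
    snr: float = 10.0
    background_level: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_clone_fraction <= 1.0):
            raise ValueError("target_clone_fraction must lie in [0, 1]")
        if len(self.shape_voxels) != 3 or any(int(s) < 16 for s in self.shape_voxels):
            raise ValueError("shape_voxels must be three integers, each >= 16")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        lo, hi = self.n_clones_range
        if lo < 1 or hi < lo:
            raise ValueError("n_clones_range must be an integer interval with lower bound >= 1")
        for d in (self.ph3_density_inside_per_mm3, self.ph3_density_outside_per_mm3):
            if not math.isfinite(d) or d < 0:
                raise ValueError("pH3 densities must be finite and >= 0")
        if not self.snr > 0:
            raise ValueError("snr must be > 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")


@dataclass
class GroundTruth:
    """True masks, clone fraction and pH3 spot positions for one phantom."""

    tissue_mask: np.ndarray
    clone_mask: np.ndarray
    clone_labels: np.ndarray
    true_fraction: float
    ph3_true_positions: np.ndarray  # (n, 3) integer voxel coords (z, y, x)
    ph3_inside: np.ndarray  # (n,) bool, True if the spot sits in a clone

    @property
    def n_ph3_inside(self) -> int:
        return int(self.ph3_inside.sum())

    @property
    def n_ph3_outside(self) -> int:
        return int((~self.ph3_inside).sum())


def make_condition_preset(name: str, **overrides) -> DiscPhantomParams:
    """Phantom parameters for a registered genotype/condition.

    The returned ``target_clone_fraction`` equals the condition's published
    mean tumor-volume fraction; all other fields take the documented
    defaults unless overridden.
    """
    if name not in VOLUME_PRESETS:
        raise KeyError(
            f"unknown condition preset {name!r}; valid names: {sorted(VOLUME_PRESETS)}"
        )
    return DiscPhantomParams(target_clone_fraction=VOLUME_PRESETS[name], **overrides)


def make_eclosion_preset(name: str, n_larvae: int = 48) -> "EclosionSimParams":
    """Eclosion simulation parameters for a registered genotype."""
    if name not in ECLOSION_PRESETS:
        raise KeyError(
            f"unknown eclosion preset {name!r}; valid names: {sorted(ECLOSION_PRESETS)}"
        )
    return EclosionSimParams(genotype=name, n_larvae=n_larvae, p_eclose=ECLOSION_PRESETS[name])


# ---------------------------------------------------------------------------
# Disc phantom rendering
# ---------------------------------------------------------------------------

def _physical_grids(shape: tuple[int, int, int], voxel: tuple[float, float, float]):
    axes = [np.arange(n) * v for n, v in zip(shape, voxel)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(grids, center_um, radii_um) -> np.ndarray:
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center_um, radii_um))
    return q <= 1.0


def _tissue_mask(params: DiscPhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Two overlapping ellipsoidal lobes with mild seeded jitter."""
    shape = params.shape_voxels
    voxel = params.voxel_size_um
    extent = np.array([n * v for n, v in zip(shape, voxel)])
    grids = _physical_grids(shape, voxel)

    def jitter(x, frac=0.06):
        return x * (1.0 + rng.uniform(-frac, frac))

    zc, yc = extent[0] / 2, extent[1] / 2
    eye_center = (jitter(zc), jitter(yc), jitter(0.64 * extent[2]))
    eye_radii = tuple(jitter(r) for r in (0.34 * extent[0], 0.33 * extent[1], 0.27 * extent[2]))
    ant_center = (jitter(zc), jitter(yc), jitter(0.30 * extent[2]))
    ant_radii = tuple(jitter(r) for r in (0.30 * extent[0], 0.24 * extent[1], 0.20 * extent[2]))
    return _ellipsoid(grids, eye_center, eye_radii) | _ellipsoid(grids, ant_center, ant_radii)


def _sigma_vox(scale_um: float, voxel: tuple[float, float, float]) -> tuple[float, ...]:
    return tuple(scale_um / v for v in voxel)


def _smooth_noise(shape, voxel, scale_um, rng) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length scale_um."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), _sigma_vox(scale_um, voxel))
    sd = f.std()
    return f / sd if sd > 0 else f


def _clone_mask(params: DiscPhantomParams, tissue: np.ndarray, rng: np.random.Generator):
    """Clone support as the top-k superlevel set of a smooth random potential.

    Seeded Gaussian bumps plus a correlated noise field give blob-shaped
    clones; selecting exactly ``round(target * |tissue|)`` tissue voxels with
    the highest potential pins the realised fraction to the target within a
    half-voxel, well inside the +/-0.01 contract.
    """
    shape = params.shape_voxels
    voxel = params.voxel_size_um
    n_tissue = int(tissue.sum())
    if n_tissue < 50:
        raise RuntimeError("degenerate phantom: tissue occupies fewer than 50 voxels")
    n_target = int(round(params.target_clone_fraction * n_tissue))
    if n_target == 0:
        return np.zeros(shape, dtype=bool)

    lo, hi = params.n_clones_range
    n_clones = int(rng.integers(lo, hi + 1))
    tissue_idx = np.argwhere(tissue)
    seeds = tissue_idx[rng.choice(len(tissue_idx), size=n_clones, replace=False)]

    grids = _physical_grids(shape, voxel)
    potential = np.zeros(shape, dtype=np.float64)
    for s in seeds:
        center = [c * v for c, v in zip(s, voxel)]
        sigma = rng.uniform(3.0, 7.0)
        amp = rng.uniform(0.8, 1.2)
        r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        potential += amp * np.exp(-r2 / (2 * sigma**2))
    potential += 0.25 * _smooth_noise(shape, voxel, 2.0, rng)

    vals = potential[tissue]
    # k-th largest potential value defines the superlevel threshold
    order = np.argsort(vals, kind="stable")[::-1][:n_target]
    clone = np.zeros(shape, dtype=bool)
    sel = tissue_idx[order]
    clone[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return clone


_CONN26 = np.ones((3, 3, 3), dtype=bool)


_PH3_MIN_SEPARATION_UM = 4.0  # ~ one nuclear diameter; mitotic nuclei cannot overlap
_PH3_PLACEMENT_TRIES = 100


def _sample_ph3(params: DiscPhantomParams, tissue, clone, rng):
    """Poisson spot counts per compartment, near-uniform positions within it.

    Counts are exactly Poisson(density x compartment volume). Positions are
    drawn by dart throwing with a hard-core minimum separation of
    3 um (mitotic nuclei are extended objects); after 100 rejected tries a
    position is accepted regardless, so the count is always preserved.
    """
    voxel_um = np.asarray(params.voxel_size_um)
    voxel_mm3 = float(np.prod(voxel_um)) / UM3_PER_MM3
    placed_um: list[np.ndarray] = []
    positions, inside_flags = [], []
    for mask, density, flag in (
        (clone, params.ph3_density_inside_per_mm3, True),
        (tissue & ~clone, params.ph3_density_outside_per_mm3, False),
    ):
        vol_mm3 = int(mask.sum()) * voxel_mm3
        n = int(rng.poisson(density * vol_mm3)) if vol_mm3 > 0 else 0
        if n == 0:
            continue
        idx = np.argwhere(mask)
        for _ in range(n):
            pick = idx[rng.integers(len(idx))]
            for _try in range(_PH3_PLACEMENT_TRIES):
                cand = idx[rng.integers(len(idx))]
                cand_um = cand * voxel_um
                if all(
                    np.linalg.norm(cand_um - q) >= _PH3_MIN_SEPARATION_UM
                    for q in placed_um
                ):
                    pick = cand
                    break
            positions.append(pick)
            placed_um.append(pick * voxel_um)
            inside_flags.append(flag)
    if positions:
        pos = np.asarray(positions, dtype=int)
    else:
        pos = np.zeros((0, 3), dtype=int)
    return pos, np.array(inside_flags, dtype=bool)


def _render_spots(shape, voxel, positions, sigma_um=1.2, amplitude=1.0):
    img = np.zeros(shape, dtype=np.float64)
    if len(positions) == 0:
        return img
    sig = _sigma_vox(sigma_um, voxel)
    half = [max(1, int(math.ceil(3 * s))) for s in sig]
    for p in positions:
        sl, local = [], []
        for ax in range(3):
            a = max(0, p[ax] - half[ax])
            b = min(shape[ax], p[ax] + half[ax] + 1)
            sl.append(slice(a, b))
            local.append((np.arange(a, b) - p[ax]) / sig[ax])
        gz, gy, gx = np.meshgrid(*local, indexing="ij")
        img[tuple(sl)] += amplitude * np.exp(-(gz**2 + gy**2 + gx**2) / 2)
    return img


def _apply_noise(clean: np.ndarray, snr: float, rng) -> np.ndarray:
    """Poisson shot noise at snr^2 photons per unit intensity + read noise."""
    scale = snr**2
    shot = rng.poisson(np.clip(clean, 0, None) * scale) / scale
    read = rng.normal(0.0, 0.5 / snr, size=clean.shape)
    return (shot + read).astype(np.float32)


def simulate_disc(params: DiscPhantomParams, seed: int) -> tuple[ImageStack, GroundTruth]:
    """Render one disc phantom and its ground truth.

    Returns an :class:`~discquant.io.ImageStack` with channels
    ``["DAPI", "GFP", "pH3"]`` and the matching :class:`GroundTruth`.
    Identical ``(params, seed)`` give bit-identical outputs.
    """
    rng = np.random.default_rng(seed)
    shape, voxel = params.shape_voxels, params.voxel_size_um
    bg = params.background_level

    tissue = _tissue_mask(params, rng)
    clone = _clone_mask(params, tissue, rng)
    labels, _ = ndimage.label(clone, structure=_CONN26)
    true_fraction = float(clone.sum()) / float(tissue.sum())
    ph3_pos, ph3_inside = _sample_ph3(params, tissue, clone, rng)

    tex_dapi = _smooth_noise(shape, voxel, 1.5, rng)
    tex_gfp = _smooth_noise(shape, voxel, 1.5, rng)
    clean_dapi = bg + tissue * np.clip(0.60 + 0.15 * tex_dapi, 0.2, 1.2)
    clean_gfp = bg + clone * np.clip(0.85 + 0.10 * tex_gfp, 0.4, 1.2)
    clean_ph3 = bg + _render_spots(shape, voxel, ph3_pos)

    stack = ImageStack(
        np.stack(
            [
                _apply_noise(clean_dapi, params.snr, rng),
                _apply_noise(clean_gfp, params.snr, rng),
                _apply_noise(clean_ph3, params.snr, rng),
            ]
        ),
        ["DAPI", "GFP", "pH3"],
        voxel,
    )
    gt = GroundTruth(
        tissue_mask=tissue,
        clone_mask=clone,
        clone_labels=labels,
        true_fraction=true_fraction,
        ph3_true_positions=ph3_pos,
        ph3_inside=ph3_inside,
    )
    return stack, gt


def ground_truth_labels(gt: GroundTruth) -> np.ndarray:
    """Training label volume from ground truth: 1 = clone, 2 = not-clone."""
    return np.where(gt.clone_mask, 1, 2).astype(np.uint8)


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountSimParams:
    """Negative-binomial count simulation with two TF modules.

    Tumor and embryo samples share an up-regulated embryonic-TF module;
    tumor samples additionally carry a down-regulated neural-TF module,
    which disc-like groups express at baseline. Module sizes default to
    62 + 62 = 124 genes, the size of the published TF signature.
    """

    n_genes: int = 2000
    groups: tuple[tuple[str, int], ...] = (
        ("embryo", 6),
        ("eye_disc", 6),
        ("tumor", 5),
        ("control", 5),
        ("other", 6),
    )
    embryonic_module_size: int = 62
    neural_module_size: int = 62
    log2fc_embryonic: float = 3.0
    log2fc_neural: float = -3.0
    dispersion: float = 0.1
    base_mean_meanlog: float = math.log(60.0)
    base_mean_sdlog: float = 1.2
    library_size_range: tuple[float, float] = (0.7, 1.4)

    def __post_init__(self) -> None:
        if self.embryonic_module_size + self.neural_module_size > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")
        if len(self.groups) < 2 or any(n < 2 for _, n in self.groups):
            raise ValueError("need >= 2 groups with >= 2 samples each")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be a positive interval")


def _gene_ids(params: CountSimParams) -> tuple[list[str], np.ndarray]:
    me, mn = params.embryonic_module_size, params.neural_module_size
    ids = (
        [f"emb{i:04d}" for i in range(me)]
        + [f"neu{i:04d}" for i in range(mn)]
        + [f"bgd{i:04d}" for i in range(params.n_genes - me - mn)]
    )
    module = np.array(["embryonic"] * me + ["neural"] * mn + ["none"] * (params.n_genes - me - mn))
    return ids, module


def simulate_expression(
    params: CountSimParams, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x samples raw count matrix plus sample metadata.

    Returns ``(counts, meta)``: counts is an integer DataFrame indexed by
    gene id (module membership is encoded in the ``emb``/``neu``/``bgd`` id
    prefixes and in ``counts.attrs["gene_module"]``); meta has one row per
    sample with its group label.
    """
    rng = np.random.default_rng(seed)
    gene_ids, module = _gene_ids(params)
    sample_ids, group_of = [], []
    for label, n in params.groups:
        for i in range(n):
            sample_ids.append(f"{label}_{i + 1}")
            group_of.append(label)
    n_s = len(sample_ids)

    base = rng.lognormal(params.base_mean_meanlog, params.base_mean_sdlog, size=params.n_genes)
    lib = rng.uniform(*params.library_size_range, size=n_s)

    lfc = np.zeros((params.n_genes, n_s))
    emb_rows = module == "embryonic"
    neu_rows = module == "neural"
    for j, g in enumerate(group_of):
        if g in ("tumor", "embryo"):
            lfc[emb_rows, j] = params.log2fc_embryonic
        if g == "tumor":
            lfc[neu_rows, j] = params.log2fc_neural

    mean = base[:, None] * lib[None, :] * np.exp2(lfc)
    # gamma-Poisson mixture == NB with var = m + dispersion * m^2
    shape = 1.0 / params.dispersion
    lam = rng.gamma(shape, mean * params.dispersion)
    counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    counts_df.attrs["gene_module"] = dict(zip(gene_ids, module))
    meta = pd.DataFrame({"sample": sample_ids, "group": group_of}).set_index("sample")
    return counts_df, meta


# ---------------------------------------------------------------------------
# Eclosion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EclosionSimParams:
    genotype: str
    n_larvae: int
    p_eclose: float

    def __post_init__(self) -> None:
        if self.n_larvae < 1:
            raise ValueError("n_larvae must be >= 1")
        if not (0.0 <= self.p_eclose <= 1.0):
            raise ValueError("p_eclose must lie in [0, 1]")


def simulate_eclosion(params: EclosionSimParams, seed: int) -> EclosionRecord:
    """Binomial survival of selected larvae to adulthood."""
    rng = np.random.default_rng(seed)
    n_adults = int(rng.binomial(params.n_larvae, params.p_eclose))
    return EclosionRecord(
        genotype=params.genotype, n_larvae=params.n_larvae, n_adults=n_adults
    )
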