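"""Synthetic cohorts with known ground truth.

Generates every input the analysis consumes: registered-subject displacement
fields carrying a programmable localized contraction of the lateral
cerebellar plate (LCeP), fluorescence channels, fragment-analysis
electropherograms, per-gene differential-expression tables for two
experiments, and qPCR Cp plates.  Every generator is a pure function of its
seed.

The displacement model is ``phi = phi_bg o phi_c``: a localized contraction
``phi_c`` (exact linear scale ``s`` inside the effect region, smoothstep
falloff outside it) composed with a smooth random background deformation
``phi_bg`` (Gaussian-correlated noise) that stands in for inter-individual
anatomical variability and registration residuals.  Amplitudes are capped so
``det grad(phi) > 0`` everywhere; offending draws are regenerated at reduced
amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .atlas import LabelAtlas, make_atlas
from .fields import DisplacementField, jacobian_determinant, warped_volumes

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSpec",
    "CohortDesign",
    "GroundTruth",
    "Subject",
    "Cohort",
    "FieldGenerationError",
    "make_subject",
    "make_cohort",
    "make_trace",
    "make_gene_tables",
    "make_qpcr",
    "Electropherogram",
]


class FieldGenerationError(RuntimeError):
    """All attempts at generating an invertible field failed."""


# ----------------------------------------------------------------------
# cohort design
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: genotype label, batch id, size, true contraction.

    ``contraction`` is the linear scale factor applied inside the effect
    region (1.0 = unaffected)."""

    genotype: str
    batch: str
    n: int
    contraction: float = 1.0


@dataclass
class CohortDesign:
    """Study conditions for a simulated registered-brain cohort.

    Defaults mirror the imaging analysis: 2 um isotropic voxels, background
    deformation with 6 um Gaussian correlation length and 0.5 um per-component
    amplitude (voxelwise LJD SD ~ 0.10), and a 10% linear LCeP contraction
    (``contraction=0.9``) for affected genotypes, set per group.
    """

    groups: list[GroupSpec]
    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    smoothness: float = 6.0  # um, Gaussian correlation length of background field
    amplitude: float = 0.5  # um, per-component SD of background displacement
    # Contraction geometry, in units of the LCeP ellipsoid quadratic form q
    # (q = 1 is the labeled LCeP surface).  The exact linear scale s applies on
    # the plateau q <= plateau_q and decays smoothly to zero over
    # [plateau_q, plateau_q + falloff_q].  The *recorded* effect region is
    # q <= effect_q; keeping effect_q + cell margin < plateau_q makes the
    # recorded region's true volume exactly s^3 times its atlas volume.
    plateau_q: float = 2.5
    falloff_q: float = 0.5
    effect_q: float = 1.75
    channels: dict[str, dict[str, float]] = field(default_factory=dict)
    channel_noise: float = 0.05  # SD of smooth intensity noise, fraction of mean
    truth_volumes: bool = True  # record per-division subject-space volumes
    max_attempts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.groups:
            if g.n < 2:
                raise ValueError(f"group {g.genotype}/{g.batch}: need n >= 2, got {g.n}")
            if not 0 < g.contraction <= 1:
                raise ValueError("contraction must be in (0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually did to one subject."""

    effect_region: np.ndarray  # boolean mask (the voxels with exact scale s)
    contraction: float
    division_volumes: dict[str, float] | None  # um^3, subject space
    total_volume: float | None  # um^3, subject space


@dataclass
class Subject:
    subject_id: str
    genotype: str
    batch: str
    field: DisplacementField
    channels: dict[str, np.ndarray]
    truth: GroundTruth
    seed_entropy: int

    _ljd_cache: object = None

    def ljd(self):
        """LJD map of this subject's field (cached)."""
        if self._ljd_cache is None:
            from .fields import log_jacobian

            self._ljd_cache = log_jacobian(self.field)
        return self._ljd_cache


@dataclass
class Cohort:
    """Subject records plus the design that produced them."""

    subjects: list[Subject]
    design: CohortDesign

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def genotypes(self) -> np.ndarray:
        return np.array([s.genotype for s in self.subjects])

    @property
    def batches(self) -> np.ndarray:
        return np.array([s.batch for s in self.subjects])

    def ljd_stack(self) -> np.ndarray:
        """(n_subjects, nx, ny, nz) array of LJD values."""
        return np.stack([s.ljd().values for s in self.subjects])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "genotype": s.genotype,
                "batch": s.batch,
                "contraction": s.truth.contraction,
                "seed_entropy": s.seed_entropy,
            }
            if s.truth.division_volumes:
                for name, v in s.truth.division_volumes.items():
                    row[f"true_vol_{name}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# displacement-field generation
# ----------------------------------------------------------------------
def _background_displacement(
    shape, spacing, smoothness: float, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian-correlated random displacement, unit-calibrated to ``amplitude``."""
    u = np.zeros(tuple(shape) + (3,))
    if amplitude == 0:
        return u
    sigma_vox = [smoothness / s for s in spacing]
    for c in range(3):
        noise = gaussian_filter(rng.standard_normal(shape), sigma_vox, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise *= amplitude / sd
        u[..., c] = noise
    return u


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _lcep_quadratic_form(atlas: LabelAtlas) -> np.ndarray:
    """Min over the two LCeP ellipsoids of the quadratic form q(x) (q<=1 inside)."""
    shape = atlas.shape
    spacing = np.asarray(atlas.spacing)
    i, j, k = np.indices(shape, dtype=float)
    coords = np.stack([i * spacing[0], j * spacing[1], k * spacing[2]], axis=-1)
    semi = np.asarray(atlas.meta["lcep_semi_vox"]) * spacing
    q = np.full(shape, np.inf)
    for center_vox in atlas.meta["lcep_centers_vox"]:
        center = np.asarray(center_vox) * spacing
        rel = coords - center
        q = np.minimum(q, ((rel / semi) ** 2).sum(axis=-1))
    return q


def effect_mask(atlas: LabelAtlas, effect_q: float = 1.75) -> np.ndarray:
    """Ground-truth effect region: voxels within ``effect_q`` of the LCeP pair."""
    return _lcep_quadratic_form(atlas) <= effect_q


def _contraction_displacement(
    atlas: LabelAtlas, contraction: float, plateau_q: float, falloff_q: float
) -> np.ndarray:
    """Displacement of a localized linear contraction of each LCeP ellipsoid.

    On the plateau (q <= plateau_q) the map is exactly ``c + s (x - c)``; the
    weight decays smoothly to zero over ``q in [plateau_q, plateau_q + falloff_q]``.
    """
    shape = atlas.shape
    spacing = np.asarray(atlas.spacing)
    i, j, k = np.indices(shape, dtype=float)
    coords = np.stack([i * spacing[0], j * spacing[1], k * spacing[2]], axis=-1)
    u = np.zeros(tuple(shape) + (3,))
    semi = np.asarray(atlas.meta["lcep_semi_vox"]) * spacing
    for center_vox in atlas.meta["lcep_centers_vox"]:
        center = np.asarray(center_vox) * spacing
        rel = coords - center
        q = ((rel / semi) ** 2).sum(axis=-1)
        w = _smoothstep((plateau_q + falloff_q - q) / falloff_q)
        u += (contraction - 1.0) * w[..., None] * rel
    return u


def _compose(outer_u: np.ndarray, inner_u: np.ndarray, spacing) -> np.ndarray:
    """Displacement of ``phi_outer o phi_inner``: u(x) = u_in(x) + u_out(x + u_in(x))."""
    shape = inner_u.shape[:3]
    idx = np.indices(shape, dtype=float)
    warped = [idx[c] + inner_u[..., c] / spacing[c] for c in range(3)]
    coords = np.stack([w.ravel() for w in warped])
    out = inner_u.copy()
    for c in range(3):
        out[..., c] += map_coordinates(
            outer_u[..., c], coords, order=1, mode="nearest"
        ).reshape(shape)
    return out


def compose_displacement(
    outer: DisplacementField, inner: DisplacementField
) -> DisplacementField:
    """Displacement field of the composition ``phi_outer o phi_inner``."""
    if outer.shape != inner.shape:
        raise ValueError("fields not congruent")
    return DisplacementField(_compose(outer.u, inner.u, inner.spacing), inner.spacing)


def make_subject(
    atlas: LabelAtlas,
    genotype: str,
    contraction: float,
    design: CohortDesign,
    seed: int | np.random.SeedSequence,
    batch: str = "b1",
    subject_id: str = "s0",
) -> Subject:
    """Generate one registered subject: field, channels and ground truth.

    The field is the composition of a smooth random background deformation
    with a localized LCeP contraction of linear scale ``contraction`` (skipped
    when ``contraction == 1``).  A draw whose Jacobian is non-positive
    anywhere is regenerated with the background amplitude reduced by 30%, up
    to ``design.max_attempts`` times.
    """
    if not 0 < contraction <= 1:
        raise ValueError("contraction must be in (0, 1]")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    shape, spacing = atlas.shape, atlas.spacing

    u_c = None
    if contraction < 1.0:
        u_c = _contraction_displacement(
            atlas, contraction, design.plateau_q, design.falloff_q
        )

    amplitude = design.amplitude
    for attempt in range(design.max_attempts):
        u_bg = _background_displacement(shape, spacing, design.smoothness, amplitude, rng)
        if u_c is None:
            u = u_bg
        else:
            u = _compose(u_bg, u_c, spacing)
        det = jacobian_determinant(DisplacementField(u, spacing))
        if det.min() > 0:
            break
        logger.warning(
            "subject %s: folded field (min det %.3g) on attempt %d; retrying at amplitude %.3g",
            subject_id,
            det.min(),
            attempt + 1,
            0.7 * amplitude,
        )
        amplitude *= 0.7
    else:
        raise FieldGenerationError(
            f"no invertible field after {design.max_attempts} attempts (subject {subject_id})"
        )

    fld = DisplacementField(u, spacing)

    channels: dict[str, np.ndarray] = {}
    for ch, means in design.channels.items():
        base = np.zeros(shape)
        scale = 0.0
        for region, mean in means.items():
            base[atlas.mask(region)] = mean
            scale = max(scale, abs(mean))
        noise = gaussian_filter(rng.standard_normal(shape), 2.0, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise *= design.channel_noise * scale / sd
        channels[ch] = base + noise

    division_volumes = None
    total = None
    if design.truth_volumes:
        masks = {name: atlas.mask(name) for name in atlas.division_names()}
        masks["__brain__"] = atlas.brain_mask()
        vols = warped_volumes(fld, masks)
        total = vols.pop("__brain__")
        division_volumes = vols

    truth = GroundTruth(
        effect_region=effect_mask(atlas, design.effect_q) if contraction < 1 else
        np.zeros(shape, dtype=bool),
        contraction=contraction,
        division_volumes=division_volumes,
        total_volume=total,
    )
    return Subject(
        subject_id=subject_id,
        genotype=genotype,
        batch=batch,
        field=fld,
        channels=channels,
        truth=truth,
        seed_entropy=int(ss.entropy) if isinstance(ss.entropy, int) else 0,
    )


def make_cohort(design: CohortDesign, atlas: LabelAtlas | None = None) -> Cohort:
    """Generate a full cohort; per-subject seeds are spawned from the master seed."""
    if atlas is None:
        atlas = make_atlas(design.shape, design.spacing)
    n_total = sum(g.n for g in design.groups)
    children = np.random.SeedSequence(design.seed).spawn(n_total)
    subjects = []
    idx = 0
    for g in design.groups:
        for r in range(g.n):
            subjects.append(
                make_subject(
                    atlas,
                    g.genotype,
                    g.contraction,
                    design,
                    children[idx],
                    batch=g.batch,
                    subject_id=f"{g.genotype}_{g.batch}_{r:02d}",
                )
            )
            idx += 1
    return Cohort(subjects=subjects, design=design)


# ----------------------------------------------------------------------
# fragment-analysis traces
# ----------------------------------------------------------------------
@dataclass
class Electropherogram:
    """Capillary-electrophoresis trace: fluorescence vs fragment size."""

    size_bp: np.ndarray
    rfu: np.ndarray
    sample_id: str = ""
    target_id: str = ""
    wt_size_bp: float | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.size_bp = np.asarray(self.size_bp, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.size_bp.shape != self.rfu.shape:
            raise ValueError("size and rfu axes differ in length")
        if np.any(np.diff(self.size_bp) <= 0):
            raise ValueError("size axis must be strictly increasing")


def make_trace(
    wt_fraction: float,
    wt_size_bp: float = 300.0,
    indel_sizes: tuple[float, ...] = (-7.0, 4.0),
    areas: tuple[float, ...] | None = None,
    noise: float = 0.5,
    seed: int = 0,
    peak_sigma_bp: float = 0.6,
    total_area: float = 1000.0,
    span_bp: float = 40.0,
    step_bp: float = 0.1,
) -> Electropherogram:
    """Synthetic electropherogram as a sum of Gaussian peaks plus baseline noise.

    ``areas`` are the relative areas of the indel peaks (normalized together
    with ``wt_fraction`` so all fractions sum to 1).  The recorded truth holds
    the normalized per-peak fractions and a ``crowded`` flag when two peaks
    sit closer than 4 peak sigmas.
    """
    if not 0 <= wt_fraction <= 1:
        raise ValueError("wt_fraction must be in [0, 1]")
    if areas is None:
        areas = tuple((1.0 - wt_fraction) / len(indel_sizes) for _ in indel_sizes)
    areas = np.asarray(areas, dtype=float)
    if np.any(areas < 0):
        raise ValueError("areas must be >= 0")
    if wt_fraction == 1.0:
        sizes = np.array([wt_size_bp])
        fracs = np.array([1.0])
    else:
        sizes = np.concatenate([[wt_size_bp], wt_size_bp + np.asarray(indel_sizes)])
        raw = np.concatenate([[wt_fraction], areas])
        keep = raw > 0
        sizes, raw = sizes[keep], raw[keep]
        fracs = raw / raw.sum()

    rng = np.random.default_rng(seed)
    lo = min(sizes.min(), wt_size_bp) - span_bp
    hi = max(sizes.max(), wt_size_bp) + span_bp
    size_axis = np.arange(lo, hi + step_bp, step_bp)
    rfu = np.zeros_like(size_axis)
    for s, f in zip(sizes, fracs):
        amp = f * total_area / (peak_sigma_bp * np.sqrt(2 * np.pi))
        rfu += amp * np.exp(-0.5 * ((size_axis - s) / peak_sigma_bp) ** 2)
    if noise > 0:
        rfu = np.clip(rfu + rng.normal(0.0, noise, size_axis.shape), 0.0, None)

    order = np.sort(sizes)
    crowded = bool(np.any(np.diff(order) < 4 * peak_sigma_bp)) if len(order) > 1 else False
    truth = {
        "peak_sizes_bp": sizes.tolist(),
        "fractions": fracs.tolist(),
        "wt_fraction": float(fracs[0] if sizes[0] == wt_size_bp else 0.0),
        "crowded": crowded,
    }
    return Electropherogram(
        size_bp=size_axis, rfu=rfu, wt_size_bp=wt_size_bp, truth=truth
    )


# ----------------------------------------------------------------------
# differential-expression tables
# ----------------------------------------------------------------------
def make_gene_tables(
    n_genes: int = 20000,
    n_true_shared: int = 31,
    n_true_private_per_expt: tuple[int, int] = (100, 820),
    lfc_effect: float = 1.0,
    base_mean_mu: float = 5.8,
    base_mean_sigma: float = 1.5,
    true_p_beta_a: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-gene statistics tables for two crispant experiments, plus truth.

    Null genes have uniform p-values and small centred log2FC; true genes have
    Beta(a, 1)-enriched p-values and |log2FC| centred on ``lfc_effect``.
    Genes true in *both* experiments get a concordant log2FC sign.  baseMean
    is lognormal so a >=100 filter leaves a realistic universe.

    Returns ``(table_a, table_b, truth)``; truth flags each gene's status in
    each experiment.
    """
    n_priv_a, n_priv_b = n_true_private_per_expt
    if n_true_shared + n_priv_a + n_priv_b > n_genes:
        raise ValueError("more true genes than genes")
    rng = np.random.default_rng(seed)
    gene_ids = np.array([f"gene{idx:05d}" for idx in range(n_genes)])

    status = np.zeros(n_genes, dtype=int)  # 0 null, 1 shared, 2 A-only, 3 B-only
    chosen = rng.choice(n_genes, n_true_shared + n_priv_a + n_priv_b, replace=False)
    status[chosen[:n_true_shared]] = 1
    status[chosen[n_true_shared : n_true_shared + n_priv_a]] = 2
    status[chosen[n_true_shared + n_priv_a :]] = 3

    base_a = rng.lognormal(base_mean_mu, base_mean_sigma, n_genes)
    base_b = rng.lognormal(base_mean_mu, base_mean_sigma, n_genes)
    shared_sign = rng.choice([-1.0, 1.0], n_genes)

    def one_table(true_mask: np.ndarray, base: np.ndarray) -> pd.DataFrame:
        p = rng.uniform(0, 1, n_genes)
        p[true_mask] = rng.beta(true_p_beta_a, 1.0, true_mask.sum())
        lfc = rng.normal(0.0, 0.15, n_genes)
        sign = np.where(status == 1, shared_sign, rng.choice([-1.0, 1.0], n_genes))
        lfc[true_mask] = (sign * (lfc_effect + rng.normal(0, 0.2, n_genes)))[true_mask]
        return pd.DataFrame(
            {"gene_id": gene_ids, "baseMean": base, "log2FoldChange": lfc, "pvalue": p}
        )

    table_a = one_table(np.isin(status, [1, 2]), base_a)
    table_b = one_table(np.isin(status, [1, 3]), base_b)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_in_a": np.isin(status, [1, 2]),
            "true_in_b": np.isin(status, [1, 3]),
            "shared": status == 1,
            "shared_sign": np.where(status == 1, shared_sign, 0.0),
        }
    )
    return table_a, table_b, truth


# ----------------------------------------------------------------------
# qPCR plates
# ----------------------------------------------------------------------
def make_qpcr(
    groups: list[tuple[str, int]],
    true_fold_change: dict[str, float],
    cp_ref_mean: float = 18.0,
    sd: float = 0.2,
    seed: int = 0,
    target_gene: str = "tp53",
    reference_gene: str = "eef1a1l1",
) -> pd.DataFrame:
    """Cp table for a relative-quantification experiment.

    For each sample, ``Cp_target = Cp_ref - log2(fold) + noise`` so the
    2^(Cp_ref - Cp_target) estimator recovers ``fold`` in expectation on the
    log2 scale.  Returns a long table (sample, group, gene, Cp).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gname, n in groups:
        fold = true_fold_change.get(gname, 1.0)
        if fold <= 0:
            raise ValueError("fold changes must be positive")
        for r in range(n):
            sample = f"{gname}_{r:02d}"
            cp_ref = cp_ref_mean + (rng.normal(0, sd) if sd > 0 else 0.0)
            cp_tgt = cp_ref - np.log2(fold) + (rng.normal(0, sd) if sd > 0 else 0.0)
            rows.append({"sample": sample, "group": gname, "gene": reference_gene, "Cp": cp_ref})
            rows.append({"sample": sample, "group": gname, "gene": target_gene, "Cp": cp_tgt})
    return pd.DataFrame(rows)


# convenience designs -------------------------------------------------------
def two_group_design(
    n_control: int = 14,
    n_crispant: int = 14,
    contraction: float = 0.9,
    batch: str = "b1",
    seed: int = 0,
    **kwargs,
) -> CohortDesign:
    """Control vs crispant design (one experiment batch)."""
    return CohortDesign(
        groups=[
            GroupSpec("ctl", batch, n_control, 1.0),
            GroupSpec("xrcc", batch, n_crispant, contraction),
        ],
        seed=seed,
        **kwargs,
    )


def rescue_design(
    n: tuple[int, int, int] = (16, 14, 12),
    contraction: float = 0.9,
    seed: int = 0,
    **kwargs,
) -> CohortDesign:
    """Three-group rescue design: control / crispant / double crispant."""
    return CohortDesign(
        groups=[
            GroupSpec("ctl", "b1", n[0], 1.0),
            GroupSpec("xrcc", "b1", n[1], contraction),
            GroupSpec("dbl", "b1", n[2], 1.0),
        ],
        seed=seed,
        **kwargs,
    )
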