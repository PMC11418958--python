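"""Seeded synthetic data with the structure the analysis modules expect.

Every generator is a pure function of its config (including the seed) and
emits the exact latent parameters it used (a *truth* object), so recovery
tests read their expected values from the truth rather than re-deriving
them.  Defaults encode the study conditions: clamp plateaus of 104.3
(euglycemic) and 301.5 mg/dL (hyperglycemic) over a 83.6 mg/dL baseline
with a 55-min breakpoint; whole-brain CMRglc near 30.7 uMol/hg/min with a
62% white-matter increase and unchanged cortex; FDG K1 of 12.67 (eu) vs
6.61 (hyper) mL/hg/min; and hexokinase isoform expression concentrated in
non-neuronal cells, microglia being the only type where HK2 outnumbers
HK1.

The image phantom is deliberately tiny (a 16 x 16 x 10 labelled box with
a white-matter core, eight gray-matter octants and three designated
reference regions); it mimics the statistical structure of the regional
data, not anatomy or scanner physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from . import fdg
from .regional import VoxelImage

__all__ = [
    "AifConfig",
    "TacDatasetConfig",
    "RegionalImageConfig",
    "ClampConfig",
    "ExpressionConfig",
    "RegionalImageTruth",
    "ClampTruth",
    "TacTruth",
    "ExpressionTruth",
    "gen_arterial_input",
    "gen_tac_dataset",
    "gen_regional_images",
    "gen_clamp_series",
    "gen_expression_matrix",
    "gen_regional_expression",
    "DEFAULT_FRAME_SCHEME",
]

# ---------------------------------------------------------------- arterial

#: 25-frame, 60-min dynamic scheme (durations in minutes).
DEFAULT_FRAME_SCHEME = tuple([10 / 60] * 6 + [30 / 60] * 6 + [1.0] * 4
                             + [3.0] * 4 + [8.0] * 5)


def _frame_starts(durations: Sequence[float]) -> np.ndarray:
    d = np.asarray(durations, float)
    return np.concatenate([[0.0], np.cumsum(d)[:-1]])


@dataclass(frozen=True)
class AifConfig:
    """Feng-style arterial input: gamma-variate bolus + triexponential tail."""

    seed: int = 0
    a1: float = 851.1  # bolus amplitude, kBq/mL/min
    a2: float = 21.9  # slow-exponential amplitudes, kBq/mL
    a3: float = 20.8
    lam1: float = 4.134  # 1/min
    lam2: float = 0.1191
    lam3: float = 0.0104
    delay: float = 0.5  # injection-to-arrival delay, min
    duration: float = 60.0
    wholeblood_ratio: float = 0.85  # whole-blood / plasma activity
    plasma_glucose: float = 5.55  # mM
    noise_sd: float = 0.0  # proportional noise


def _feng_curve(cfg: AifConfig, t: np.ndarray) -> np.ndarray:
    ts = np.maximum(t - cfg.delay, 0.0)
    curve = ((cfg.a1 * ts - cfg.a2 - cfg.a3) * np.exp(-cfg.lam1 * ts)
             + cfg.a2 * np.exp(-cfg.lam2 * ts) + cfg.a3 * np.exp(-cfg.lam3 * ts))
    curve[t <= cfg.delay] = 0.0
    return np.maximum(curve, 0.0)


def gen_arterial_input(config: AifConfig = AifConfig()) -> fdg.ArterialInput:
    """Simulate hand-drawn arterial sampling: dense early, sparse late."""
    cfg = config
    times = np.concatenate([
        np.arange(0.0, 3.0, 5 / 60),  # every 5 s over the bolus
        np.arange(3.0, 10.0, 0.5),
        np.arange(10.0, cfg.duration + 1e-9, 5.0),
    ])
    plasma = _feng_curve(cfg, times)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        plasma = np.maximum(plasma * (1 + cfg.noise_sd * rng.standard_normal(times.size)), 0.0)
    wholeblood = plasma * cfg.wholeblood_ratio
    return fdg.ArterialInput(times, plasma, wholeblood,
                             plasma_glucose=cfg.plasma_glucose)


# ---------------------------------------------------------------- TACs


@dataclass(frozen=True)
class TacDatasetConfig:
    """Replicated noisy TACs from known two-tissue parameters."""

    seed: int = 0
    params_eu: fdg.TwoTissueParams = field(
        default_factory=lambda: fdg.TwoTissueParams(12.67, 0.35, 0.10, 0.011, 0.05))
    params_hyper: fdg.TwoTissueParams = field(
        default_factory=lambda: fdg.TwoTissueParams(6.61, 0.20, 0.06, 0.008, 0.05))
    noise: float = 0.05  # proportional Gaussian noise on frame activities
    n_replicates: int = 10
    frame_durations: tuple[float, ...] = DEFAULT_FRAME_SCHEME
    aif: AifConfig = field(default_factory=AifConfig)


@dataclass(frozen=True)
class TacTruth:
    params: dict[str, fdg.TwoTissueParams]
    noise: float
    noiseless: dict[str, fdg.TimeActivityCurve]


def gen_tac_dataset(config: TacDatasetConfig = TacDatasetConfig()
                    ) -> tuple[dict[str, list[fdg.TimeActivityCurve]],
                               fdg.ArterialInput, TacTruth]:
    """Noisy replicate TACs per condition plus the generating truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    input_ = gen_arterial_input(cfg.aif)
    starts = _frame_starts(cfg.frame_durations)
    durations = np.asarray(cfg.frame_durations, float)
    params = {"eu": cfg.params_eu, "hyper": cfg.params_hyper}
    clean = {cond: fdg.model_tac(p, input_, starts, durations, label=cond)
             for cond, p in params.items()}
    tacs: dict[str, list[fdg.TimeActivityCurve]] = {}
    for cond, base in clean.items():
        reps = []
        for r in range(cfg.n_replicates):
            noisy = base.activity * (1 + cfg.noise * rng.standard_normal(base.activity.size))
            reps.append(fdg.TimeActivityCurve(starts, durations,
                                              np.maximum(noisy, 0.0),
                                              label=f"{cond}_{r}"))
        tacs[cond] = reps
    return tacs, input_, TacTruth(params=params, noise=cfg.noise, noiseless=clean)


# ---------------------------------------------------------------- images

#: Gray-matter octant region names; the first three are the designated
#: metabolically-stable reference regions.
GRAY_REGIONS = ("middle_temporal", "lateral_orbitofrontal", "postcentral",
                "precuneus", "putamen", "cerebellum_cortex",
                "superior_frontal", "lateral_occipital")
WHITE_REGION = "deep_white"


@dataclass(frozen=True)
class RegionalImageConfig:
    """Paired-condition metabolic phantom images.

    Baselines put whole-brain CMRglc near 30.7 uMol/hg/min with a ~1.7
    gray/white contrast.  Hyperglycemia multiplies white matter by
    ``white_scale`` (62% increase by default) and leaves every gray
    region's mean exactly unchanged; the three designated reference
    regions additionally reuse the euglycemic noise realisation, so their
    observed change is exactly zero (the metabolically stable anchor the
    reference-selection step is meant to find), while the remaining gray
    regions are exact nulls with independent noise.
    """

    seed: int = 0
    shape: tuple[int, int, int] = (16, 16, 10)
    n_subjects: int = 8
    gray_baseline: float = 32.0  # uMol/hg/min
    white_baseline: float = 19.0
    region_baseline_sd: float = 1.5  # between-region baseline spread (gray)
    white_scale: float = 1.62
    subject_sd: float = 1.5  # random intercept SD
    voxel_noise_sd: float = 1.0
    n_unpaired: int = 0  # subjects with only one condition


@dataclass(frozen=True)
class RegionalImageTruth:
    reference_labels: tuple[str, ...]
    white_label: str
    white_mask: np.ndarray
    region_baseline: dict[str, float]
    region_delta: dict[str, float]
    white_scale: float
    subject_intercepts: dict[str, float]
    voxel_noise_sd: float


def _phantom_parcellation(shape: tuple[int, int, int]
                          ) -> tuple[np.ndarray, pd.DataFrame]:
    """Label volume: central white core, eight gray octants around it."""
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=int)
    # gray octants, ids 2..9
    octant = ((np.arange(nx)[:, None, None] >= nx // 2) * 4
              + (np.arange(ny)[None, :, None] >= ny // 2) * 2
              + (np.arange(nz)[None, None, :] >= nz // 2) * 1)
    labels[:] = octant + 2
    # white core, id 1 (overwrites the centre)
    cx, cy, cz = nx // 4, ny // 4, nz // 4
    labels[cx:nx - cx, cy:ny - cy, cz:nz - cz] = 1
    names = [WHITE_REGION] + list(GRAY_REGIONS)
    lookup = pd.DataFrame({"label_id": range(1, 10), "name": names})
    return labels, lookup


def gen_regional_images(config: RegionalImageConfig = RegionalImageConfig()
                        ) -> tuple[list[tuple[str, str, VoxelImage]],
                                   VoxelImage, pd.DataFrame, pd.DataFrame,
                                   RegionalImageTruth]:
    """Generate (subject, condition, image) triplets plus parcellation.

    Returns ``(images, parcellation, lookup, regional_table, truth)``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    labels, lookup = _phantom_parcellation(cfg.shape)
    name_of = dict(zip(lookup["label_id"], lookup["name"]))

    region_baseline: dict[str, float] = {WHITE_REGION: cfg.white_baseline}
    for name in GRAY_REGIONS:
        region_baseline[name] = cfg.gray_baseline \
            + cfg.region_baseline_sd * rng.standard_normal()

    reference = GRAY_REGIONS[:3]
    region_delta: dict[str, float] = {name: 0.0 for name in GRAY_REGIONS}
    region_delta[WHITE_REGION] = (cfg.white_scale - 1.0) * cfg.white_baseline

    subjects = [f"sub{i:02d}" for i in range(cfg.n_subjects)]
    intercepts = {s: cfg.subject_sd * rng.standard_normal() for s in subjects}

    base_map = np.zeros(cfg.shape)
    delta_map = np.zeros(cfg.shape)
    for label_id, name in name_of.items():
        sel = labels == label_id
        base_map[sel] = region_baseline[name]
        delta_map[sel] = region_delta[name]

    ref_ids = [int(lookup.loc[lookup["name"] == n, "label_id"].iloc[0])
               for n in reference]
    ref_mask = np.isin(labels, ref_ids)

    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    images: list[tuple[str, str, VoxelImage]] = []
    rows = []
    for i, subj in enumerate(subjects):
        conds = ("eu", "hyper")
        if cfg.n_unpaired and i < cfg.n_unpaired:
            conds = ("eu",) if i % 2 == 0 else ("hyper",)
        eu_data = None
        for cond in conds:
            mean = base_map + (delta_map if cond == "hyper" else 0.0) + intercepts[subj]
            data = mean + cfg.voxel_noise_sd * rng.standard_normal(cfg.shape)
            if cond == "eu":
                eu_data = data
            elif eu_data is not None:
                # reference regions are metabolically stable by construction
                data[ref_mask] = eu_data[ref_mask]
            img = VoxelImage(data, affine, modality="cmrglc")
            images.append((subj, cond, img))
            for label_id, name in name_of.items():
                rows.append({"subject": subj, "condition": cond, "region": name,
                             "value": float(data[labels == label_id].mean()),
                             "modality": "cmrglc"})

    parcellation = VoxelImage(labels.astype(float), affine, modality="parcellation")
    truth = RegionalImageTruth(
        reference_labels=tuple(reference), white_label=WHITE_REGION,
        white_mask=labels == 1, region_baseline=region_baseline,
        region_delta=region_delta, white_scale=cfg.white_scale,
        subject_intercepts=intercepts, voxel_noise_sd=cfg.voxel_noise_sd)
    return images, parcellation, lookup, pd.DataFrame(rows), truth


# ---------------------------------------------------------------- clamp


@dataclass(frozen=True)
class ClampConfig:
    """Piecewise-linear clamp series at the study's plateaus."""

    seed: int = 0
    n_subjects: int = 10
    times: tuple[float, ...] = tuple(np.arange(0.0, 116.0, 5.0))
    breakpoint: float = 55.0
    baseline: float = 83.6  # mg/dL, both conditions
    plateau_eu: float = 104.3  # value reached at the breakpoint
    plateau_hyper: float = 301.5
    post_slope_eu: float = -0.05  # slow drift after the breakpoint, mg/dL/min
    post_slope_hyper: float = -0.07
    subject_sd: float = 3.0
    visit_sd: float = 2.0
    resid_sd: float = 4.0


@dataclass(frozen=True)
class ClampTruth:
    fixed_effects: dict[str, float]  # keyed like clamp.DESIGN_COLUMNS
    breakpoint: float
    subject_sd: float
    visit_sd: float
    resid_sd: float


def gen_clamp_series(config: ClampConfig = ClampConfig()
                     ) -> tuple[pd.DataFrame, ClampTruth]:
    """Tidy clamp series (one visit per condition per subject) + truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    slope_eu = (cfg.plateau_eu - cfg.baseline) / cfg.breakpoint
    slope_hyper = (cfg.plateau_hyper - cfg.baseline) / cfg.breakpoint
    beta = {
        "intercept": cfg.baseline,
        "cond_hyper": 0.0,
        "time": slope_eu,
        "time_x_hyper": slope_hyper - slope_eu,
        "hinge_eu": cfg.post_slope_eu - slope_eu,
        "hinge_hyper": cfg.post_slope_hyper - slope_hyper,
    }
    t = np.asarray(cfg.times, float)
    hinge = np.maximum(0.0, t - cfg.breakpoint)
    rows = []
    for i in range(cfg.n_subjects):
        subj = f"sub{i:02d}"
        b_subj = cfg.subject_sd * rng.standard_normal()
        for visit, cond in enumerate(("eu", "hyper")):
            b_visit = cfg.visit_sd * rng.standard_normal()
            hyper = 1.0 if cond == "hyper" else 0.0
            mean = (beta["intercept"] + beta["cond_hyper"] * hyper
                    + (beta["time"] + beta["time_x_hyper"] * hyper) * t
                    + (beta["hinge_hyper"] if hyper else beta["hinge_eu"]) * hinge)
            values = mean + b_subj + b_visit \
                + cfg.resid_sd * rng.standard_normal(t.size)
            for time, val in zip(t, values):
                rows.append({"subject": subj, "visit": f"v{visit}",
                             "condition": cond, "time": float(time),
                             "analyte": "glucose", "value": float(val)})
    truth = ClampTruth(fixed_effects=beta, breakpoint=cfg.breakpoint,
                       subject_sd=cfg.subject_sd, visit_sd=cfg.visit_sd,
                       resid_sd=cfg.resid_sd)
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------- expression


@dataclass(frozen=True)
class ExpressionConfig:
    """Bernoulli-thinned sparse counts with cell-type-specific isoform use.

    Default probabilities make HK2 essentially absent from neurons,
    enriched in astrocytes, and the majority isoform only in microglia.
    """

    seed: int = 0
    n_cells: int = 5000
    cell_types: tuple[str, ...] = ("neuron", "astrocyte", "microglia",
                                   "oligodendrocyte", "opc", "endothelial")
    proportions: tuple[float, ...] = (0.55, 0.12, 0.08, 0.15, 0.05, 0.05)
    neuronal_types: tuple[str, ...] = ("neuron",)
    #: per-type expression probability for each isoform
    probabilities: tuple[tuple[str, tuple[float, ...]], ...] = (
        ("HK1", (0.55, 0.45, 0.30, 0.45, 0.35, 0.30)),
        ("HK2", (0.004, 0.18, 0.42, 0.06, 0.05, 0.08)),
        ("HK3", (0.01, 0.01, 0.12, 0.01, 0.01, 0.01)),
        ("GCK", (0.002, 0.002, 0.002, 0.002, 0.002, 0.002)),
    )
    n_filler_genes: int = 16
    mean_count: float = 2.0  # mean positive count of an expressing cell


@dataclass(frozen=True)
class ExpressionTruth:
    probabilities: dict[str, dict[str, float]]  # gene -> type -> P(express)
    type_counts: dict[str, int]


def gen_expression_matrix(config: ExpressionConfig = ExpressionConfig()):
    """Sparse genes x cells counts, labels, and generating probabilities."""
    from .expression import ExpressionMatrix

    cfg = config
    probs = dict(cfg.probabilities)
    for gene, p in probs.items():
        arr = np.asarray(p, float)
        if arr.size != len(cfg.cell_types) or np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"probabilities for {gene} must be in [0,1], "
                             f"one per cell type")
    rng = np.random.default_rng(cfg.seed)
    types = rng.choice(len(cfg.cell_types), size=cfg.n_cells,
                       p=np.asarray(cfg.proportions) / np.sum(cfg.proportions))
    type_names = np.asarray(cfg.cell_types)[types]
    classes = np.where(np.isin(type_names, cfg.neuronal_types),
                       "neuronal", "non-neuronal")

    gene_names = list(probs) + [f"FILLER{i:02d}" for i in range(cfg.n_filler_genes)]
    rows, cols, data = [], [], []
    for g_idx, gene in enumerate(gene_names):
        if gene in probs:
            p_cell = np.asarray(probs[gene], float)[types]
        else:
            p_cell = np.full(cfg.n_cells, 0.2)
        on = rng.random(cfg.n_cells) < p_cell
        idx = np.flatnonzero(on)
        counts = 1 + rng.poisson(cfg.mean_count - 1.0, size=idx.size)
        rows.extend([g_idx] * idx.size)
        cols.extend(idx.tolist())
        data.extend(counts.tolist())
    counts = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(gene_names), cfg.n_cells))
    cells = pd.DataFrame({"cell_type": type_names, "cell_class": classes,
                          "region": "phantom"})
    truth = ExpressionTruth(
        probabilities={g: dict(zip(cfg.cell_types, p)) for g, p in probs.items()},
        type_counts={t: int(np.sum(type_names == t)) for t in cfg.cell_types})
    return ExpressionMatrix(counts, pd.Index(gene_names), cells), truth


def gen_regional_expression(delta: pd.DataFrame, target_r: float = -0.63,
                            seed: int = 0, num_gene: str = "HK1",
                            den_gene: str = "HK2") -> pd.DataFrame:
    """Regional isoform expression whose ratio tracks a metabolic map.

    A seeded Gaussian copula couples the ``num_gene``/``den_gene``
    log-ratio to the given per-region values (column ``delta``) at
    population correlation ``target_r``; the realised sample correlation
    then scatters around it.  Returns a tidy frame ``region, gene,
    expression``.
    """
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target_r must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    values = delta["delta"].to_numpy(float)
    z = (values - values.mean()) / values.std()
    ratio_z = target_r * z + np.sqrt(1 - target_r ** 2) * rng.standard_normal(z.size)
    log_ratio = 0.5 * ratio_z  # modest dynamic range
    den = np.exp(0.3 * rng.standard_normal(z.size))  # HK2 level, positive
    num = den * np.exp(log_ratio)
    rows = []
    for region, n_val, d_val in zip(delta["region"], num, den):
        rows.append({"region": region, "gene": num_gene, "expression": float(n_val)})
        rows.append({"region": region, "gene": den_gene, "expression": float(d_val)})
    return pd.DataFrame(rows)
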