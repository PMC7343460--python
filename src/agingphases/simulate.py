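"""Synthetic multi-omics cohorts with known aging-phase structure.

The generator emulates the statistical structure the downstream
analysis assumes: a cohort of ~86 adults sampled uniformly over
21–76 years, whose *biological* age is a noisy version of chronological
age; four latent aging phases defined as equal-width bins of biological
age; phase-patterned "informative" gene sets whose per-phase activity
follows one of three archetypes (primary / secondary / integrative);
CpG clock features drifting linearly with biological age; additive
per-batch shifts; and inflated residual variance (transcriptional
noise) for subjects in the last phase.

Every run is fully reproducible from the config seed, and the returned
:class:`SyntheticTruth` carries the ground truth every downstream stage
is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    BETA,
    EXPRESSION,
    LOG2_TPM,
    M_VALUE,
    METHYLATION,
    ClockModel,
    GeneSet,
    GeneSetCollection,
    OmicsMatrix,
)

#: Per-phase activity of the three hallmark archetypes (4 phases).
#: primary peaks in phases 2–3 then drops; secondary rises sharply at
#: phase 3; integrative rises monotonically and peaks in phase 4.
DEFAULT_ARCHETYPES: dict[str, tuple[float, ...]] = {
    "primary": (0.30, 1.00, 0.70, 0.20),
    "secondary": (0.15, 0.30, 1.00, 0.55),
    "integrative": (0.20, 0.35, 0.65, 1.00),
}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the cohort the analysis is designed for: 86
    subjects aged 21–76, four latent phases along a biological-age axis
    with ~4 y of chronological/biological decoupling, nine informative
    gene sets (three per archetype), two measurement batches, and a
    doubling of residual noise in the last phase.
    """

    n_subjects: int = 86
    age_range: tuple[float, float] = (21.0, 76.0)
    n_phases: int = 4
    bio_age_sd: float = 4.0
    n_genes: int = 2000
    n_cpgs: int = 4000
    n_informative_sets: int = 9
    set_size: int = 20
    profile_archetypes: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES))
    effect_size: float = 2.0
    batch_count: int = 2
    batch_shift_sd: float = 0.3
    phase4_noise_factor: float = 2.0
    clock_cpg_count: int = 200
    clock_slope_sd: float = 0.02  # M-value drift per year; per-CpG age
    # correlation stays modest (clocks recover age by averaging CpGs)
    # phase-patterned CpG modules: the methylome's own discrete phase
    # signal (epigenetic remodeling), without which the fused network
    # would carry latent phases in one view only
    n_informative_cpgs: int = 500
    meth_effect_size: float = 2.0
    # residual-noise model: per-feature SDs are lognormal so that the
    # top-MAD tail is enriched for the phase-informative features, as in
    # real transcriptomes where age-regulated genes are high-variance
    expr_noise_median: float = 0.25
    expr_noise_spread: float = 0.30
    meth_noise_median: float = 0.35
    meth_noise_spread: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.phase4_noise_factor < 1.0:
            raise ValueError("phase4_noise_factor must be >= 1")
        if self.effect_size < 0.0:
            raise ValueError("effect_size must be >= 0")
        if self.age_range[1] <= self.age_range[0]:
            raise ValueError("age_range must be increasing")
        for name, profile in self.profile_archetypes.items():
            if len(profile) != self.n_phases:
                raise ValueError(
                    f"archetype {name!r} profile length {len(profile)} != n_phases")
        if self.n_informative_sets * self.set_size > self.n_genes:
            raise ValueError("informative sets require more genes than available")
        if self.clock_cpg_count + self.n_informative_cpgs > self.n_cpgs:
            raise ValueError("clock and informative CpGs exceed n_cpgs")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    subjects: pd.DataFrame  # subject_id, chron_age, bio_age, phase, batch
    set_archetypes: dict[str, str]  # gene set name -> archetype
    informative_genes: dict[str, tuple[str, ...]]
    clock: ClockModel

    @property
    def phases(self) -> pd.Series:
        return pd.Series(self.subjects["phase"].to_numpy(),
                         index=self.subjects["subject_id"], name="phase")

    @property
    def bio_age(self) -> pd.Series:
        return pd.Series(self.subjects["bio_age"].to_numpy(),
                         index=self.subjects["subject_id"], name="bio_age")


@dataclass
class _CohortModel:
    """Frozen per-feature parameters, retained so a follow-up visit can
    be simulated from the same generative model."""

    gene_ids: list[str]
    cpg_ids: list[str]
    gene_baseline: np.ndarray
    gene_noise_sd: np.ndarray
    gene_effect: np.ndarray  # genes × phases mean shift
    cpg_baseline: np.ndarray
    cpg_noise_sd: np.ndarray
    cpg_slope: np.ndarray  # per-CpG M-value drift per year of bio age
    cpg_effect: np.ndarray  # cpgs × phases mean shift
    batch_labels: list[str]
    gene_batch_shift: np.ndarray  # batches × genes
    cpg_batch_shift: np.ndarray
    age_mid: float


@dataclass
class Cohort:
    expr: OmicsMatrix
    meth: OmicsMatrix
    metadata: pd.DataFrame
    gene_sets: GeneSetCollection
    clock: ClockModel
    truth: SyntheticTruth
    config: CohortConfig
    model: _CohortModel


def phase_of_bio_age(bio_age, age_range: tuple[float, float], n_phases: int):
    """Phase label (1..n_phases) = equal-width bin of biological age.

    Bin edges divide ``age_range`` evenly; ages outside the range fall
    into the first/last bin.  The thresholds are fixed by the config,
    so the label is a deterministic function of biological age.
    """
    lo, hi = age_range
    width = (hi - lo) / n_phases
    idx = np.floor((np.asarray(bio_age, dtype=float) - lo) / width).astype(int)
    return np.clip(idx, 0, n_phases - 1) + 1


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a cohort with latent aging-phase structure.

    Returns expression (log2-TPM), methylation (M values), metadata,
    the informative gene-set collection, a linear M-value clock whose
    target is biological age, and the ground truth.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    lo, hi = cfg.age_range

    subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    chron = rng.uniform(lo, hi, size=n)
    bio = chron + rng.normal(0.0, cfg.bio_age_sd, size=n)
    phase = phase_of_bio_age(bio, cfg.age_range, cfg.n_phases)
    batch_labels = [f"B{i + 1}" for i in range(cfg.batch_count)]
    batch = np.array(batch_labels)[rng.permuted(np.arange(n) % cfg.batch_count)]

    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    cpg_ids = [f"cg{i + 1:06d}" for i in range(cfg.n_cpgs)]

    # archetype assignment: informative sets cycle primary, secondary, ...
    archetype_names = list(cfg.profile_archetypes)
    counters = {a: 0 for a in archetype_names}
    sets: list[GeneSet] = []
    set_archetypes: dict[str, str] = {}
    informative: dict[str, tuple[str, ...]] = {}
    pool = rng.permutation(cfg.n_genes)
    gene_effect = np.zeros((cfg.n_genes, cfg.n_phases))
    for s in range(cfg.n_informative_sets):
        arch = archetype_names[s % len(archetype_names)]
        counters[arch] += 1
        name = f"{arch}_{counters[arch]}"
        members = np.sort(pool[s * cfg.set_size:(s + 1) * cfg.set_size])
        genes = tuple(gene_ids[g] for g in members)
        sets.append(GeneSet(name, f"synthetic {arch} hallmark set", genes))
        set_archetypes[name] = arch
        informative[name] = genes
        profile = np.asarray(cfg.profile_archetypes[arch], dtype=float)
        # per-gene direction: roughly half the set is down-regulated
        sign = rng.choice([-1.0, 1.0], size=len(members))
        gene_effect[members] = sign[:, None] * cfg.effect_size * profile[None, :]

    gene_baseline = rng.normal(7.0, 2.0, size=cfg.n_genes)
    gene_noise_sd = cfg.expr_noise_median * np.exp(
        rng.normal(0.0, cfg.expr_noise_spread, size=cfg.n_genes))

    cpg_baseline = rng.normal(0.0, 2.0, size=cfg.n_cpgs)
    cpg_noise_sd = cfg.meth_noise_median * np.exp(
        rng.normal(0.0, cfg.meth_noise_spread, size=cfg.n_cpgs))
    cpg_slope = np.zeros(cfg.n_cpgs)
    clock_idx = np.arange(cfg.clock_cpg_count)
    cpg_slope[clock_idx] = rng.normal(0.0, cfg.clock_slope_sd, size=cfg.clock_cpg_count)

    # phase-patterned CpG modules (disjoint from the clock CpGs), one
    # archetype per module, mirroring the expression signal structure
    cpg_effect = np.zeros((cfg.n_cpgs, cfg.n_phases))
    if cfg.n_informative_cpgs:
        if cfg.clock_cpg_count + cfg.n_informative_cpgs > cfg.n_cpgs:
            raise ValueError("clock and informative CpGs exceed n_cpgs")
        inf_idx = cfg.clock_cpg_count + np.arange(cfg.n_informative_cpgs)
        per_mod = max(1, cfg.n_informative_cpgs // len(archetype_names))
        for j, idx in enumerate(inf_idx):
            arch = archetype_names[min(j // per_mod, len(archetype_names) - 1)]
            profile = np.asarray(cfg.profile_archetypes[arch], dtype=float)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            cpg_effect[idx] = sign * cfg.meth_effect_size * profile

    gene_batch_shift = rng.normal(0.0, cfg.batch_shift_sd,
                                  size=(cfg.batch_count, cfg.n_genes))
    cpg_batch_shift = rng.normal(0.0, cfg.batch_shift_sd,
                                 size=(cfg.batch_count, cfg.n_cpgs))

    age_mid = 0.5 * (lo + hi)
    model = _CohortModel(
        gene_ids=gene_ids, cpg_ids=cpg_ids,
        gene_baseline=gene_baseline, gene_noise_sd=gene_noise_sd,
        gene_effect=gene_effect,
        cpg_baseline=cpg_baseline, cpg_noise_sd=cpg_noise_sd,
        cpg_slope=cpg_slope, cpg_effect=cpg_effect,
        batch_labels=batch_labels,
        gene_batch_shift=gene_batch_shift, cpg_batch_shift=cpg_batch_shift,
        age_mid=age_mid,
    )

    expr_vals, meth_vals = _simulate_matrices(model, cfg, bio, phase, batch, rng)

    batch_series = pd.Series(batch, index=subject_ids, name="batch")
    expr = OmicsMatrix(pd.DataFrame(expr_vals, index=gene_ids, columns=subject_ids),
                       kind=EXPRESSION, scale=LOG2_TPM, batch=batch_series)
    meth = OmicsMatrix(pd.DataFrame(meth_vals, index=cpg_ids, columns=subject_ids),
                       kind=METHYLATION, scale=M_VALUE, batch=batch_series)

    # linear clock inverting the clock-CpG drift model:
    # m = b + s*(bio - age_mid) + e  =>  bio ~ age_mid + sum w*(m - b)
    s = cpg_slope[clock_idx]
    w = s / float(np.sum(s**2))
    coef = pd.Series(w, index=[cpg_ids[i] for i in clock_idx])
    intercept = age_mid - float(np.sum(w * cpg_baseline[clock_idx]))
    clock = ClockModel(intercept=intercept, coefficients=coef, input_scale=M_VALUE)

    metadata = pd.DataFrame({
        "subject_id": subject_ids,
        "chron_age": chron,
        "batch": batch,
        "timepoint": 1,
        "bmi": rng.normal(24.0, 3.0, size=n).round(1),
        "frequent_sunbathing": rng.integers(0, 2, size=n),
    })
    truth = SyntheticTruth(
        subjects=pd.DataFrame({
            "subject_id": subject_ids,
            "chron_age": chron,
            "bio_age": bio,
            "phase": phase,
            "batch": batch,
        }),
        set_archetypes=set_archetypes,
        informative_genes=informative,
        clock=clock,
    )
    return Cohort(expr=expr, meth=meth, metadata=metadata,
                  gene_sets=GeneSetCollection(sets), clock=clock,
                  truth=truth, config=cfg, model=model)


def _simulate_matrices(model: _CohortModel, cfg: CohortConfig,
                       bio: np.ndarray, phase: np.ndarray, batch: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = len(bio)
    noise_scale = np.where(phase == cfg.n_phases, cfg.phase4_noise_factor, 1.0)
    batch_idx = np.array([model.batch_labels.index(b) for b in batch])

    expr = (model.gene_baseline[:, None]
            + model.gene_effect[:, phase - 1]
            + model.gene_batch_shift[batch_idx].T
            + rng.normal(size=(cfg.n_genes, n))
            * model.gene_noise_sd[:, None] * noise_scale[None, :])

    meth = (model.cpg_baseline[:, None]
            + model.cpg_effect[:, phase - 1]
            + model.cpg_slope[:, None] * (bio - model.age_mid)[None, :]
            + model.cpg_batch_shift[batch_idx].T
            + rng.normal(size=(cfg.n_cpgs, n))
            * model.cpg_noise_sd[:, None] * noise_scale[None, :])
    return expr, meth


def generate_followup(cohort: Cohort, years: float = 3.0,
                      n_subjects: int = 31, seed: int = 0) -> Cohort:
    """Re-measure a subset of the cohort after ``years`` of aging.

    Biological and chronological age advance by ``years``; matrices are
    re-simulated from the same per-feature generative model (new
    measurement noise, a fresh follow-up batch shift), and phases are
    re-derived from the fixed biological-age thresholds.
    """
    cfg = cohort.config
    rng = np.random.default_rng(seed)
    base = cohort.truth.subjects
    if n_subjects > len(base):
        raise ValueError("follow-up subset larger than cohort")
    pick = np.sort(rng.choice(len(base), size=n_subjects, replace=False))
    sub = base.iloc[pick].reset_index(drop=True)

    chron = sub["chron_age"].to_numpy() + years
    bio = sub["bio_age"].to_numpy() + years
    phase = phase_of_bio_age(bio, cfg.age_range, cfg.n_phases)
    batch = sub["batch"].to_numpy()

    expr_vals, meth_vals = _simulate_matrices(cohort.model, cfg, bio, phase, batch, rng)
    ids = sub["subject_id"].tolist()
    batch_series = pd.Series(batch, index=ids, name="batch")
    expr = OmicsMatrix(pd.DataFrame(expr_vals, index=cohort.model.gene_ids, columns=ids),
                       kind=EXPRESSION, scale=LOG2_TPM, batch=batch_series)
    meth = OmicsMatrix(pd.DataFrame(meth_vals, index=cohort.model.cpg_ids, columns=ids),
                       kind=METHYLATION, scale=M_VALUE, batch=batch_series)
    metadata = pd.DataFrame({
        "subject_id": ids, "chron_age": chron, "batch": batch, "timepoint": 2,
    })
    truth = SyntheticTruth(
        subjects=pd.DataFrame({
            "subject_id": ids, "chron_age": chron, "bio_age": bio,
            "phase": phase, "batch": batch,
        }),
        set_archetypes=cohort.truth.set_archetypes,
        informative_genes=cohort.truth.informative_genes,
        clock=cohort.clock,
    )
    return Cohort(expr=expr, meth=meth, metadata=metadata,
                  gene_sets=cohort.gene_sets, clock=cohort.clock,
                  truth=truth, config=cfg, model=cohort.model)


def generate_null_sets(gene_ids: list[str], collection: GeneSetCollection,
                       n: int, size: int, seed: int = 0) -> GeneSetCollection:
    """Draw ``n`` gene sets of ``size`` genes carrying no phase signal.

    The pool is every gene not present in ``collection``; drawing is
    uniform without replacement within each set.  Used as negative
    controls for predictivity analysis.
    """
    informative = collection.all_genes()
    pool = sorted(set(gene_ids) - informative)
    if size > len(pool):
        raise ValueError(f"requested set size {size} exceeds null pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n):
        genes = tuple(sorted(rng.choice(pool, size=size, replace=False)))
        sets.append(GeneSet(f"null_{i + 1}", "random non-informative genes", genes))
    return GeneSetCollection(sets)


def beta_from_m(m: np.ndarray) -> np.ndarray:
    """Inverse-logistic map from M values to beta values."""
    return 1.0 / (1.0 + 2.0 ** (-np.asarray(m, dtype=float)))
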