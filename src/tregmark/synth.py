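"""Synthetic data with planted ground truth for every pipeline stage.

Four generators emulate the four data regimes the marker screen consumes:

* :func:`simulate_bulk` — negative-binomial bulk RNA-seq counts over six
  CD4+ T-cell populations (tumor-infiltrating and spleen-derived Tregs and
  conventional T cells from tumor-bearing and normal mice) with surface-gene
  markers induced only in the tumor-infiltrating Treg population and
  coregulated gene modules driven by shared latent factors.
* :func:`simulate_singlecell` — zero-inflated counts over the four presorted
  human populations (tumor Treg, adjacent-normal Treg, blood Treg, tumor
  conventional T helper) with markers induced only in tumor Tregs.
* :func:`simulate_microarray` — log-normal intensities over naive, acute- and
  chronic-infection Treg conditions, with a chronic-specific set and a
  chronic+acute shared set to exercise the signature-subtraction rule.
* :func:`simulate_cohort` — survival cohorts whose hazard is a power of a
  per-subject Treg-normalized marker score, plus therapy-response labels.

All randomness flows from ``SimConfig.seed`` through named substreams, so any
stage can be regenerated independently and bit-identically.

Realism choices (defaults; see docs/methods.md): dispersion 0.05 as for sorted
pure populations from inbred mice, gene abundances log2-normal(6, 1.5), module
genes at log2-normal(7, 0.5) with a 1.5-log2-unit latent amplitude, library
sizes log-normal with CV 0.2, microarray replicate noise 0.35 log2 units.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .diffexp import ExpressionMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "SurvivalCohort",
    "BULK_POPULATIONS",
    "SC_POPULATIONS",
    "ARRAY_CONDITIONS",
    "simulate_bulk",
    "simulate_singlecell",
    "simulate_microarray",
    "simulate_cohort",
]

BULK_POPULATIONS = (
    "TBM-TI-Treg",
    "TBM-TI-Tconv",
    "TBM-SP-Treg",
    "NM-SP-Treg",
    "TBM-SP-Tconv",
    "NM-SP-Tconv",
)
TI_TREG = "TBM-TI-Treg"
SC_POPULATIONS = ("TTR", "NTR", "PTR", "TTH")
ARRAY_CONDITIONS = ("chronic", "acute", "naive")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Counts are genes; proportions in [0, 1]; effect sizes in log2 units.
    ``populations`` maps population label -> replicate count (bulk mode);
    ``module_spec`` lists (hub id or None for auto, module size, within-module
    Pearson correlation of the latent log-expression).  ``dropout_logit`` is
    (intercept, slope) of the detection-probability logit against log2 mean
    expression in single-cell mode; None disables dropout.
    """

    n_genes: int = 2000
    populations: dict[str, int] = field(
        default_factory=lambda: {p: 3 for p in BULK_POPULATIONS}
    )
    surface_fraction: float = 0.15
    n_planted_markers: int = 30
    marker_log2fc: float = 2.0
    marker_mean_log2: float = 7.0
    marker_mean_log2_sd: float = 0.5
    nb_dispersion: float = 0.01
    module_spec: list[tuple[str | None, int, float]] = field(
        default_factory=lambda: [(None, 20, 0.9)] * 5
    )
    signature_overlap: float = 0.5
    dropout_logit: tuple[float, float] | None = (-1.0, 0.8)
    cells_per_population: int = 200
    array_replicates: int = 5
    n_chronic_specific: int = 40
    n_shared: int = 20
    array_effect_log2: float = 2.0
    array_noise_sd: float = 0.35
    n_negative_markers: int = 6
    conserved_fraction: float = 0.5
    mean_log2: float = 6.0
    mean_log2_sd: float = 1.5
    module_mean_log2: float = 7.0
    module_mean_log2_sd: float = 0.5
    module_sd_log2: float = 1.5
    library_size_cv: float = 0.2
    cohort_n: int = 300
    hazard_ratio: float = 2.5
    censor_rate: float = 0.3
    baseline_median_survival: float = 24.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for frac_name in (
            "surface_fraction",
            "signature_overlap",
            "censor_rate",
            "conserved_fraction",
        ):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1], got {v}")
        if self.n_planted_markers < 0 or self.n_planted_markers > int(
            self.surface_fraction * self.n_genes
        ):
            raise ValueError("n_planted_markers must fit inside the surface gene set")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for pop, reps in self.populations.items():
            if reps < 2:
                raise ValueError(
                    f"population {pop!r} has {reps} replicate(s); at least 2 are "
                    "required for variance estimation"
                )
        for _, size, rho in self.module_spec:
            if size < 2 or not 0.0 <= rho < 1.0:
                raise ValueError("module size must be >= 2 and correlation in [0, 1)")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, order-independent substream of the config seed."""
        key = zlib.crc32(stream.encode("utf8"))
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside each synthetic dataset."""

    planted_marker_ids: frozenset[str] = frozenset()
    hub_ids: frozenset[str] = frozenset()
    module_membership: dict[str, str] = field(default_factory=dict)
    signature_ids: frozenset[str] = frozenset()
    cohort_betas: dict[str, float] = field(default_factory=dict)
    surface_ids: frozenset[str] = frozenset()
    negative_marker_ids: frozenset[str] = frozenset()
    chronic_specific_ids: frozenset[str] = frozenset()
    shared_ids: frozenset[str] = frozenset()


@dataclass
class SurvivalCohort:
    """Per-subject follow-up times, events and marker/normalizer expression.

    ``data`` columns: subject, time, event (1 = death observed, 0 =
    censored), response (1 = therapy responder), marker_expr,
    normalizer_expr, optional stage.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "time", "event", "marker_expr", "normalizer_expr"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if (self.data["time"] < 0).any():
            raise ValueError("negative follow-up times")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")
        if (self.data[["marker_expr", "normalizer_expr"]] < 0).to_numpy().any():
            raise ValueError("expression values must be non-negative")


def _gene_ids(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _assign_roles(config: SimConfig, rng: np.random.Generator, prefix: str = "G"):
    """Partition gene indices into surface/marker/module/negative-marker roles."""
    ids = np.array(_gene_ids(config.n_genes, prefix))
    n_surface = int(round(config.surface_fraction * config.n_genes))
    perm = rng.permutation(config.n_genes)
    surface_idx = perm[:n_surface]
    marker_idx = surface_idx[: config.n_planted_markers]
    remaining = perm[n_surface:]
    pos = 0
    modules: list[tuple[str, np.ndarray, float]] = []
    for k, (hub, size, rho) in enumerate(config.module_spec):
        members = remaining[pos : pos + size]
        if members.size < size:
            raise ValueError("not enough genes to place all modules")
        pos += size
        hub_id = hub if hub is not None else str(ids[members[0]])
        modules.append((hub_id, members, rho))
        if hub is not None:
            ids[members[0]] = hub
    neg_idx = remaining[pos : pos + config.n_negative_markers]
    pos += config.n_negative_markers
    return ids, surface_idx, marker_idx, modules, neg_idx


def _nb_counts(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson (negative binomial) sampling: var = mu + dispersion*mu^2."""
    if dispersion == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_bulk(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Six-population bulk RNA-seq counts with planted markers and modules.

    Planted markers are surface genes whose log2 mean is raised by
    ``marker_log2fc`` in the tumor-infiltrating Treg population only.  Module
    genes share a per-sample Gaussian latent factor on the log2-mean scale:
    with amplitude s and within-module correlation rho each member's log2 mean
    gains ``s*(sqrt(rho)*F + sqrt(1-rho)*eps)``, giving latent pairwise
    correlation exactly rho.  Negative-marker genes (non-T-cell lineage) sit
    at a ~1-count floor.  Library sizes are log-normal (CV per config).
    """
    config.validate()
    required = set(BULK_POPULATIONS) - set(config.populations)
    if required:
        raise ValueError(f"bulk simulation requires populations {sorted(required)}")
    rng = config.rng("bulk")
    ids, surface_idx, marker_idx, modules, neg_idx = _assign_roles(config, rng)

    base = rng.normal(config.mean_log2, config.mean_log2_sd, size=config.n_genes)
    # planted markers emulate abundantly expressed Treg surface genes: a 4-fold
    # induction on a handful of counts is not a screenable marker
    base[marker_idx] = rng.normal(
        config.marker_mean_log2, config.marker_mean_log2_sd, size=marker_idx.size
    )
    for _, members, _ in modules:
        base[members] = rng.normal(
            config.module_mean_log2, config.module_mean_log2_sd, size=members.size
        )
    base[neg_idx] = 0.0  # ~1 count: the technical noise floor

    samples, pops = [], []
    for pop, reps in config.populations.items():
        for r in range(1, reps + 1):
            samples.append(f"{pop}_r{r}")
            pops.append(pop)
    n_samples = len(samples)

    log2mu = np.tile(base[:, None], (1, n_samples))
    is_ti_treg = np.array([p == TI_TREG for p in pops])
    log2mu[np.ix_(marker_idx, is_ti_treg)] += config.marker_log2fc
    # the hub carries the module's latent factor with loading 1 (it drives the
    # module); members load sqrt(rho), so member-member latent correlation is
    # rho and hub-member correlation sqrt(rho) — hub edges are the strongest
    s = config.module_sd_log2
    for _, members, rho in modules:
        factor = rng.normal(size=n_samples)
        noise = rng.normal(size=(members.size - 1, n_samples))
        log2mu[members[0]] += s * factor
        log2mu[members[1:]] += s * (np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * noise)

    sigma = np.sqrt(np.log(1.0 + config.library_size_cv**2))
    lib = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_samples))
    mu = lib[None, :] * 2.0**log2mu
    counts = _nb_counts(mu, config.nb_dispersion, rng)

    values = pd.DataFrame(counts, index=ids, columns=samples)
    meta = pd.DataFrame(
        {
            "population": pops,
            "tissue": ["tumor" if "TI" in p else "spleen" for p in pops],
            "condition": ["tumor-bearing" if p.startswith("TBM") else "normal" for p in pops],
            "replicate": [int(sid.rsplit("_r", 1)[1]) for sid in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    membership = {
        str(ids[m]): hub for hub, members, _ in modules for m in members
    }
    # context signature: a fixed fraction of each module's non-hub members
    signature: set[str] = set()
    for hub, members, _ in modules:
        member_ids = [str(ids[m]) for m in members if str(ids[m]) != hub]
        k = int(round(config.signature_overlap * len(member_ids)))
        signature.update(member_ids[:k])
    truth = SimTruth(
        planted_marker_ids=frozenset(ids[marker_idx]),
        hub_ids=frozenset(h for h, _, _ in modules),
        module_membership=membership,
        signature_ids=frozenset(signature),
        surface_ids=frozenset(ids[surface_idx]),
        negative_marker_ids=frozenset(ids[neg_idx]),
    )
    mat = ExpressionMatrix(values, meta, scale="count")
    return mat, truth


def simulate_singlecell(
    config: SimConfig, marker_ids: list[str] | None = None
) -> tuple[ExpressionMatrix, SimTruth]:
    """Zero-inflated single-cell counts over the four presorted populations.

    Counts are negative binomial on a lower-abundance scale (bulk log2 mean
    shifted down 4 units), thinned by a dropout process: each gene's detection
    probability is ``expit(intercept + slope * log2(mu + 1))``, so lowering
    the intercept raises the observed zero fraction.  Markers (human ids
    ``H...``, or the supplied ``marker_ids``) are induced in tumor Tregs
    (TTR) only.
    """
    config.validate()
    rng = config.rng("singlecell")
    ids = np.array(_gene_ids(config.n_genes, prefix="H"))
    if marker_ids is None:
        marker_idx = rng.choice(config.n_genes, size=config.n_planted_markers, replace=False)
    else:
        lookup = {g: i for i, g in enumerate(ids)}
        missing = [g for g in marker_ids if g not in lookup]
        if missing:
            raise ValueError(f"marker ids not in gene universe: {missing[:5]}")
        marker_idx = np.array([lookup[g] for g in marker_ids], dtype=int)

    base = rng.normal(config.mean_log2 - 4.0, config.mean_log2_sd, size=config.n_genes)
    cells, pops = [], []
    for pop in SC_POPULATIONS:
        for c in range(1, config.cells_per_population + 1):
            cells.append(f"{pop}_c{c:04d}")
            pops.append(pop)
    n_cells = len(cells)

    log2mu = np.tile(base[:, None], (1, n_cells))
    is_ttr = np.array([p == "TTR" for p in pops])
    log2mu[np.ix_(marker_idx, is_ttr)] += config.marker_log2fc
    sigma = np.sqrt(np.log(1.0 + config.library_size_cv**2))
    lib = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_cells))
    mu = lib[None, :] * 2.0**log2mu
    counts = _nb_counts(mu, config.nb_dispersion, rng).astype(float)

    if config.dropout_logit is not None:
        intercept, slope = config.dropout_logit
        detect = special.expit(intercept + slope * np.log2(mu + 1.0))
        if not np.all(np.isfinite(detect)) or np.any(detect <= 0) or np.any(detect >= 1):
            raise ValueError("dropout probability outside (0, 1) after transform")
        counts *= rng.random(size=counts.shape) < detect

    values = pd.DataFrame(counts.astype(int), index=ids, columns=cells)
    meta = pd.DataFrame(
        {
            "population": pops,
            "tissue": [
                {"TTR": "tumor", "NTR": "normal", "PTR": "blood", "TTH": "tumor"}[p]
                for p in pops
            ],
            "condition": ["NSCLC"] * n_cells,
            "replicate": [1] * n_cells,
        },
        index=pd.Index(cells, name="sample"),
    )
    truth = SimTruth(planted_marker_ids=frozenset(ids[marker_idx]))
    return ExpressionMatrix(values, meta, scale="count"), truth


def simulate_microarray(
    config: SimConfig,
    chronic_ids: list[str] | None = None,
    shared_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Log-normal microarray intensities over chronic/acute/naive conditions.

    One planted set is elevated in the chronic condition only (the
    chronic-specific truth); a second set is elevated in both chronic and
    acute, so that subtracting acute-vs-naive DEGs from chronic-vs-naive DEGs
    removes it.  Values are log2 intensities with i.i.d. Gaussian replicate
    noise.  Gene ids share the bulk mouse universe (``G...``) so signatures
    intersect across platforms; explicit ``chronic_ids``/``shared_ids`` may
    pin the planted sets to chosen genes (e.g., the bulk planted markers).
    """
    config.validate()
    rng = config.rng("microarray")
    ids = np.array(_gene_ids(config.n_genes, prefix="G"))
    lookup = {g: i for i, g in enumerate(ids)}

    def resolve(requested: list[str] | None, n_default: int, taken: set[int]) -> np.ndarray:
        if requested is not None:
            missing = [g for g in requested if g not in lookup]
            if missing:
                raise ValueError(f"planted ids not in gene universe: {missing[:5]}")
            return np.array([lookup[g] for g in requested], dtype=int)
        free = np.array([i for i in rng.permutation(config.n_genes) if i not in taken])
        return free[:n_default]

    chronic_idx = resolve(chronic_ids, config.n_chronic_specific, set())
    shared_idx = resolve(shared_ids, config.n_shared, set(chronic_idx))
    if set(chronic_idx) & set(shared_idx):
        raise ValueError("chronic-specific and shared planted sets must be disjoint")

    base = rng.normal(config.mean_log2, config.mean_log2_sd, size=config.n_genes)
    samples, conds = [], []
    for cond in ARRAY_CONDITIONS:
        for r in range(1, config.array_replicates + 1):
            samples.append(f"{cond}_r{r}")
            conds.append(cond)
    log2i = np.tile(base[:, None], (1, len(samples)))
    cond_arr = np.array(conds)
    log2i[np.ix_(chronic_idx, cond_arr == "chronic")] += config.array_effect_log2
    for cond in ("chronic", "acute"):
        log2i[np.ix_(shared_idx, cond_arr == cond)] += config.array_effect_log2
    log2i += rng.normal(0.0, config.array_noise_sd, size=log2i.shape)

    values = pd.DataFrame(log2i, index=ids, columns=samples)
    meta = pd.DataFrame(
        {
            "population": conds,
            "tissue": ["spleen"] * len(samples),
            "condition": conds,
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    truth = SimTruth(
        chronic_specific_ids=frozenset(ids[chronic_idx]),
        shared_ids=frozenset(ids[shared_idx]),
    )
    return ExpressionMatrix(values, meta, scale="log-intensity"), truth


def _uniform_censor_bound(lams: np.ndarray, target: float) -> float:
    """Upper bound tau of Uniform(0, tau) censoring giving the target rate.

    For T ~ Exp(lam) and independent C ~ U(0, tau), P(C < T) =
    (1 - exp(-lam*tau)) / (lam*tau); the returned tau matches the average
    censoring probability over the cohort's hazards.
    """

    def frac(tau: float) -> float:
        z = lams * tau
        return float(np.mean((1.0 - np.exp(-z)) / z))

    lo, hi = 1e-9, 1.0
    while frac(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            break
    return float(optimize.brentq(lambda t: frac(t) - target, lo, hi))


def simulate_cohort(config: SimConfig) -> tuple[SurvivalCohort, SimTruth]:
    """Survival cohort whose hazard is a power of the marker score.

    Per-subject latent score z ~ N(0, 1); event times are exponential with
    hazard ``lambda0 * hazard_ratio**z`` (lambda0 set by the baseline median
    survival).  Censoring is independent Uniform(0, tau) with tau calibrated
    to the configured censoring fraction.  Therapy response is Bernoulli with
    log-odds ``-z`` (high marker score, low response).  Marker and normalizer
    expression are constructed so that the log2 marker/normalizer ratio
    recovers z up to the pseudocount.
    """
    config.validate()
    if config.hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if config.cohort_n < 20:
        raise ValueError("cohort_n must be at least 20")
    rng = config.rng("cohort")
    n = config.cohort_n
    z = rng.normal(size=n)
    lam0 = np.log(2.0) / config.baseline_median_survival
    lam = lam0 * config.hazard_ratio**z
    t_event = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        tau = _uniform_censor_bound(lam, config.censor_rate)
        c = rng.uniform(0.0, tau, size=n)
    else:
        c = np.full(n, np.inf)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    response = (rng.random(n) < special.expit(-z)).astype(int)
    u = rng.normal(5.0, 1.0, size=n)
    normalizer = 2.0**u
    marker = 2.0 ** (u + z)
    stage = np.where(special.expit(z + rng.normal(scale=1.0, size=n)) > 0.5, "IV", "I")
    data = pd.DataFrame(
        {
            "subject": [f"S{i:04d}" for i in range(1, n + 1)],
            "time": time,
            "event": event,
            "response": response,
            "marker_expr": marker,
            "normalizer_expr": normalizer,
            "stage": stage,
        }
    )
    truth = SimTruth(
        cohort_betas={"log_hazard_per_unit_score": float(np.log(config.hazard_ratio))}
    )
    return SurvivalCohort(data), truth
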