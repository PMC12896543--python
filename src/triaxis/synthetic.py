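"""Synthetic cohort, single-cell, and pseudobulk generators.

Every downstream stage of the pipeline (signature scoring, discovery
modelling, leave-one-cohort-out validation, deconvolution, platform
simulation) is exercised against data produced here, so the generators
plant *known* effects that the analysis code must recover:

* a bulk immunotherapy cohort in which the focal marker (``BCL2A1``),
  ``CD274`` and a correlated "hot" immune-activation gene program are
  mean-shifted in responders, and survival follows an exponential model
  with a known hazard ratio per standard deviation of focal expression;
* a panel of batch-shifted external validation cohorts sharing that
  effect structure;
* a labelled CD8+ T-cell population with subtype-specific marker genes,
  a focal-marker-positive subcompartment, and responder-enriched
  subtypes;
* exact linear pseudobulk mixtures for deconvolution oracles.

Expression is modelled on the log2 scale as Gaussian per gene with
gene-level means drawn from Uniform(2, 10) and unit residual variance;
the hot program shares a one-factor latent structure giving a tunable
pairwise correlation. These choices keep every planted effect available
in closed form for tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FOCAL_GENE = "BCL2A1"
CD274_GENE = "CD274"

__all__ = [
    "FOCAL_GENE",
    "CD274_GENE",
    "SimulationConfig",
    "CellConfig",
    "CohortBundle",
    "CellTable",
    "hot_gene_names",
    "generate_bulk_cohort",
    "generate_multi_cohort",
    "generate_cell_population",
    "generate_pseudobulk",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_clinical_csv",
    "read_clinical_csv",
]


def hot_gene_names(n: int = 27) -> list[str]:
    """Names of the synthetic hot-program genes (``HOT01`` ... )."""
    return [f"HOT{i + 1:02d}" for i in range(n)]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic bulk cohort generator.

    Parameters
    ----------
    n_genes : int
        Total genes in the matrix (focal + CD274 + hot program + filler).
    n_samples : int
        Cohort size; the discovery stand-in uses 60.
    responder_fraction : float
        Fraction of samples labelled responder, in (0, 1).
    marker_effect : float
        Log2 fold-change added to the focal marker in responders.
    cd274_effect : float
        Log2 fold-change added to CD274 in responders (an independent
        second axis of planted signal).
    hot_effect : float or None
        Log2 fold-change added to every hot-program gene in responders;
        ``None`` means "same as marker_effect".
    hot_gene_count : int
        Size of the co-activated hot program (default 27).
    hot_correlation : float
        Pairwise correlation of hot-program genes, in [0, 1).
    survival_hr : float
        Hazard ratio per +1 SD of focal-marker expression (values < 1
        mean high expression is protective).
    censor_rate : float
        Fraction of samples administratively censored, in [0, 1).
    seed : int
        Seed; a fixed seed gives byte-identical output.
    """

    n_genes: int = 1000
    n_samples: int = 60
    responder_fraction: float = 0.4
    marker_effect: float = 1.0
    cd274_effect: float = 1.0
    hot_effect: float | None = None
    hot_gene_count: int = 27
    hot_correlation: float = 0.6
    survival_hr: float = 0.43
    censor_rate: float = 0.3
    baseline_median_months: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.hot_gene_count + 2:
            raise ValueError("n_genes must cover focal, CD274 and hot genes")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not 0.0 < self.responder_fraction < 1.0:
            raise ValueError("responder_fraction must be in (0, 1)")
        n_resp = int(round(self.n_samples * self.responder_fraction))
        if n_resp == 0 or n_resp == self.n_samples:
            raise ValueError("responder_fraction yields an empty class")
        if not 0.0 <= self.hot_correlation < 1.0:
            raise ValueError("hot_correlation must be in [0, 1)")
        if self.survival_hr <= 0:
            raise ValueError("survival_hr must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")

    @property
    def resolved_hot_effect(self) -> float:
        return self.marker_effect if self.hot_effect is None else self.hot_effect


@dataclass
class CohortBundle:
    """One cohort: expression (genes x samples, log2), labels, survival."""

    cohort_id: str
    expression: pd.DataFrame
    response: pd.Series
    surv_time: pd.Series
    surv_event: pd.Series
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if self.response.isna().any():
            raise ValueError("response labels must not be missing")
        if self.expression.index.duplicated().any():
            raise ValueError("duplicate gene names")
        if self.expression.columns.duplicated().any():
            raise ValueError("duplicate sample names")
        if (self.surv_time < 0).any():
            raise ValueError("survival times must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def samples(self) -> pd.Index:
        return self.expression.columns


def _gene_names(config: SimulationConfig) -> list[str]:
    names = [FOCAL_GENE, CD274_GENE] + hot_gene_names(config.hot_gene_count)
    n_fill = config.n_genes - len(names)
    names += [f"G{i + 1:04d}" for i in range(n_fill)]
    return names


def generate_bulk_cohort(
    config: SimulationConfig,
    cohort_id: str = "discovery",
    rng: np.random.Generator | None = None,
) -> CohortBundle:
    """Simulate one bulk cohort with planted tri-axis response signal.

    Responders have the focal marker, CD274 and every hot-program gene
    mean-shifted by the configured log2 effects.  Hot-program genes share
    a per-sample latent factor giving pairwise correlation
    ``hot_correlation`` with unit marginal variance.  Survival times are
    exponential with log-hazard ``log(survival_hr)`` per SD of focal
    expression; censoring is administrative at the empirical survival
    quantile that censors ``censor_rate`` of the cohort.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _gene_names(config)
    n_genes, n = config.n_genes, config.n_samples
    samples = pd.Index([f"{cohort_id}_S{i + 1:03d}" for i in range(n)], name="sample")

    n_resp = int(round(n * config.responder_fraction))
    response = np.zeros(n, dtype=int)
    response[rng.permutation(n)[:n_resp]] = 1

    base_mean = rng.uniform(2.0, 10.0, size=n_genes)
    x = base_mean[:, None] + rng.standard_normal((n_genes, n))

    # hot program: one-factor model, unit marginal variance
    rho = config.hot_correlation
    factor = rng.standard_normal(n)
    hot_rows = slice(2, 2 + config.hot_gene_count)
    x[hot_rows] = (
        base_mean[hot_rows.start : hot_rows.stop, None]
        + np.sqrt(rho) * factor[None, :]
        + np.sqrt(1.0 - rho) * rng.standard_normal((config.hot_gene_count, n))
    )

    x[0] += config.marker_effect * response
    x[1] += config.cd274_effect * response
    x[hot_rows] += config.resolved_hot_effect * response[None, :]

    expr = pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=samples)

    focal = x[0]
    z = (focal - focal.mean()) / focal.std()
    lam0 = np.log(2.0) / config.baseline_median_months
    hazard = lam0 * np.exp(np.log(config.survival_hr) * z)
    t_true = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        cutoff = np.quantile(t_true, 1.0 - config.censor_rate)
        event = (t_true <= cutoff).astype(int)
        time = np.minimum(t_true, cutoff)
    else:
        event = np.ones(n, dtype=int)
        time = t_true

    covariates = pd.DataFrame(
        {
            "stage_bin": rng.integers(0, 2, size=n),
            "line_bin": rng.integers(0, 2, size=n),
        },
        index=samples,
    )
    return CohortBundle(
        cohort_id=cohort_id,
        expression=expr,
        response=pd.Series(response, index=samples, name="response"),
        surv_time=pd.Series(time, index=samples, name="surv_time"),
        surv_event=pd.Series(event, index=samples, name="surv_event"),
        covariates=covariates,
    )


def generate_multi_cohort(
    config: SimulationConfig,
    n_cohorts: int = 5,
    sizes: Sequence[int] = (56, 14, 22, 7, 27),
    batch_sd: float = 0.5,
) -> list[CohortBundle]:
    """Simulate heterogeneous external cohorts sharing the effect structure.

    Each cohort is an independent draw from the configured generative
    model at its own size, then shifted by an independent per-gene batch
    offset ~ Normal(0, batch_sd^2) on the log2 scale.
    """
    if len(sizes) != n_cohorts:
        raise ValueError("sizes length must equal n_cohorts")
    if batch_sd < 0:
        raise ValueError("batch_sd must be non-negative")
    seeds = np.random.SeedSequence(config.seed).spawn(n_cohorts)
    cohorts = []
    for i, (size, ss) in enumerate(zip(sizes, seeds)):
        sub = dataclasses.replace(config, n_samples=int(size))
        rng = np.random.default_rng(ss)
        bundle = generate_bulk_cohort(sub, cohort_id=f"val{i + 1}", rng=rng)
        offsets = rng.normal(0.0, batch_sd, size=bundle.expression.shape[0])
        bundle.expression = bundle.expression.add(offsets, axis=0)
        cohorts.append(bundle)
    return cohorts


DEFAULT_SUBTYPES = (
    "Trm",
    "Tcm",
    "Teff_Memory",
    "Teff_Activated",
    "Proliferating",
    "Tex",
    "Terminally_Differentiated",
)


@dataclass(frozen=True)
class CellConfig:
    """Parameters of the synthetic CD8+ cell-population generator.

    The real population this emulates is two orders of magnitude larger;
    the statistical structure (subtype marker programs, a focal-positive
    subcompartment concentrated in designated subtypes, responder-shifted
    subtype frequencies) is identical at desk scale.

    ``focal_program_corr`` is the loading of a shared per-cell
    activation factor on the focal gene and the markers of the focal
    subtypes (log2 scale), making the focal marker *redundant* with its
    program — the structure the dropNB reference-ablation analysis
    probes.  The default loading puts the focal-marker/program-marker
    Pearson correlation (log scale, among focal-positive cells) in the
    0.5-0.6 range.
    """

    subtypes: tuple[str, ...] = DEFAULT_SUBTYPES
    n_cells: int = 3000
    n_patients: int = 10
    mpr_fraction: float = 0.5
    markers_per_subtype: int = 12
    marker_lfc: float = 2.0
    n_background_genes: int = 120
    enriched_subtypes: tuple[str, ...] = ("Trm", "Proliferating")
    enrichment: float = 2.0
    focal_subtypes: tuple[str, ...] = ("Trm", "Proliferating")
    focal_positive_rate: tuple[float, float] = (0.6, 0.1)
    focal_program_corr: float = 1.3
    marker_genes: Mapping[str, tuple[str, ...]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.subtypes) < 3:
            raise ValueError("need at least 3 subtypes")
        if self.markers_per_subtype < 10:
            raise ValueError("need >= 10 marker genes per subtype")
        if self.n_patients < 4:
            raise ValueError("need >= 4 patients")
        if not 0.0 < self.mpr_fraction < 1.0:
            raise ValueError("mpr_fraction must be in (0, 1)")
        if self.marker_genes is not None:
            all_markers = [g for gs in self.marker_genes.values() for g in gs]
            if len(all_markers) != len(set(all_markers)):
                raise ValueError("overlapping marker assignments between subtypes")

    def resolved_markers(self) -> dict[str, tuple[str, ...]]:
        if self.marker_genes is not None:
            return {s: tuple(g) for s, g in self.marker_genes.items()}
        return {
            s: tuple(f"{s}_M{j + 1:02d}" for j in range(self.markers_per_subtype))
            for s in self.subtypes
        }


@dataclass
class CellTable:
    """Labelled single cells with linear-scale expression (cells x genes)."""

    cell_id: pd.Index
    patient_id: pd.Series
    response_label: pd.Series  # 1 = MPR
    subtype: pd.Series
    expression: pd.DataFrame
    focal_positive: pd.Series
    planted_markers: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = self.subtype.value_counts()
        if (counts < 2).any():
            raise ValueError("each subtype needs >= 2 cells")
        focal = self.expression[FOCAL_GENE] > 0
        if not (focal == self.focal_positive.astype(bool)).all():
            raise ValueError("focal_positive inconsistent with focal expression")

    @property
    def subtypes(self) -> list[str]:
        return sorted(self.subtype.unique())

    def patient_composition(self) -> pd.DataFrame:
        """Per-patient subtype fractions (patients x subtypes)."""
        tab = pd.crosstab(self.patient_id, self.subtype)
        return tab.div(tab.sum(axis=1), axis=0)

    def patient_labels(self) -> pd.Series:
        return self.response_label.groupby(self.patient_id).first()


def generate_cell_population(config: CellConfig) -> CellTable:
    """Simulate a labelled CD8+ cell population.

    Each subtype over-expresses its own marker genes by ``marker_lfc``
    on the log2 scale; MPR patients carry ``enrichment``-fold higher
    frequency weights for the enriched subtypes; the focal marker is
    expressed (non-zero) preferentially in the focal subtypes and its
    log-expression co-varies with the focal subtypes' markers through a
    shared activation factor.
    """
    rng = np.random.default_rng(config.seed)
    markers = config.resolved_markers()
    marker_union = [g for s in config.subtypes for g in markers.get(s, ())]
    genes = (
        [FOCAL_GENE]
        + marker_union
        + [f"BG{i + 1:04d}" for i in range(config.n_background_genes)]
    )
    gene_index = pd.Index(genes, name="gene")

    n_mpr = int(round(config.n_patients * config.mpr_fraction))
    patient_resp = np.zeros(config.n_patients, dtype=int)
    patient_resp[:n_mpr] = 1
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]

    # per-patient subtype weights; MPR patients up-weight enriched subtypes
    base_w = np.ones(len(config.subtypes))
    enriched_idx = [config.subtypes.index(s) for s in config.enriched_subtypes]

    cell_patient = rng.integers(0, config.n_patients, size=config.n_cells)
    subtype_codes = np.empty(config.n_cells, dtype=int)
    for p in range(config.n_patients):
        w = base_w.copy()
        if patient_resp[p] == 1:
            w[enriched_idx] *= config.enrichment
        w = w / w.sum()
        mask = cell_patient == p
        subtype_codes[mask] = rng.choice(len(config.subtypes), size=mask.sum(), p=w)
    # guarantee every subtype is populated
    for k in range(len(config.subtypes)):
        if (subtype_codes == k).sum() < 2:
            subtype_codes[rng.permutation(config.n_cells)[:2]] = k

    base_mean = rng.uniform(1.0, 6.0, size=len(genes))
    log2x = base_mean[None, :] + rng.standard_normal((config.n_cells, len(genes)))

    gene_pos = {g: i for i, g in enumerate(genes)}
    for s, gs in markers.items():
        k = config.subtypes.index(s)
        in_s = subtype_codes == k
        for g in gs:
            log2x[in_s, gene_pos[g]] += config.marker_lfc

    # focal gene: activation factor shared with focal-subtype markers
    activation = rng.standard_normal(config.n_cells)
    focal_idx = gene_pos[FOCAL_GENE]
    in_focal_sub = np.isin(
        subtype_codes, [config.subtypes.index(s) for s in config.focal_subtypes]
    )
    log2x[:, focal_idx] += config.marker_lfc * in_focal_sub
    log2x[:, focal_idx] += config.focal_program_corr * activation
    for s in config.focal_subtypes:
        for g in markers[s]:
            log2x[:, gene_pos[g]] += config.focal_program_corr * activation

    rate_in, rate_out = config.focal_positive_rate
    p_pos = np.where(in_focal_sub, rate_in, rate_out)
    focal_pos = rng.random(config.n_cells) < p_pos

    lin = np.maximum(np.exp2(log2x) - 1.0, 0.0)
    lin[~focal_pos, focal_idx] = 0.0
    lin[focal_pos, focal_idx] = np.maximum(lin[focal_pos, focal_idx], 1e-6)

    cell_ids = pd.Index([f"C{i + 1:05d}" for i in range(config.n_cells)], name="cell")
    expr = pd.DataFrame(lin, index=cell_ids, columns=gene_index)
    pid = pd.Series([patients[i] for i in cell_patient], index=cell_ids, name="patient")
    return CellTable(
        cell_id=cell_ids,
        patient_id=pid,
        response_label=pd.Series(
            patient_resp[cell_patient], index=cell_ids, name="response"
        ),
        subtype=pd.Series(
            [config.subtypes[c] for c in subtype_codes], index=cell_ids, name="subtype"
        ),
        expression=expr,
        focal_positive=pd.Series(focal_pos.astype(int), index=cell_ids, name="focal_positive"),
        planted_markers=markers,
    )


def generate_pseudobulk(
    reference,
    fractions: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Linear mixture of reference columns plus optional Gaussian noise.

    ``reference`` is a gene x subtype DataFrame (or an object with a
    ``.data`` DataFrame attribute).  Fractions must be non-negative and
    sum to at most 1; the remainder is unexplained "other" mass that
    contributes nothing to the mixture.
    """
    data = getattr(reference, "data", reference)
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 1 or len(f) != data.shape[1]:
        raise ValueError("fractions length must match reference columns")
    if (f < 0).any() or f.sum() > 1.0 + 1e-9:
        raise ValueError("fractions must be >= 0 and sum to <= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vec = data.to_numpy() @ f
    if noise_sd > 0:
        vec = vec + rng.normal(0.0, noise_sd, size=len(vec))
    return pd.Series(vec, index=data.index, name="pseudobulk")


# ---------------------------------------------------------------------------
# plain-text IO


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_clinical_csv(bundle: CohortBundle, path) -> None:
    tab = pd.DataFrame(
        {
            "response": bundle.response,
            "surv_time": bundle.surv_time,
            "surv_event": bundle.surv_event,
        }
    ).join(bundle.covariates)
    tab.to_csv(path, index_label="sample")


def read_clinical_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample")
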