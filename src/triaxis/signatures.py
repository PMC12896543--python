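"""Gene-signature scoring and hot/cold classification.

A signature is a named gene set with an optional per-gene direction;
the default scoring rule is the mean of per-gene z-scores (computed
across samples), which is scale-free and standard for small immune
signatures.  Benchmark immunotherapy signatures (TIDE, TIS, IPS, IFNG)
are registry entries scored by the same operation: their gene lists are
configuration, not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .synthetic import CD274_GENE, FOCAL_GENE, hot_gene_names

__all__ = [
    "SignatureDefinition",
    "SignatureScores",
    "score_signature",
    "classify_hot_cold",
    "make_negative_controls",
    "default_hot_signature",
    "load_signature_registry",
    "write_signature_registry",
    "bundled_registry",
]


@dataclass(frozen=True)
class SignatureDefinition:
    """A named gene list with scoring method and per-gene direction."""

    name: str
    genes: tuple[str, ...]
    method: str = "mean_z"
    directions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("signature needs at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")
        if self.method not in ("mean_z", "mean_log"):
            raise ValueError(f"unknown scoring method {self.method!r}")
        if self.directions and len(self.directions) != len(self.genes):
            raise ValueError("directions length must match genes")

    @property
    def resolved_directions(self) -> np.ndarray:
        if self.directions:
            return np.asarray(self.directions, dtype=float)
        return np.ones(len(self.genes))

    def subset(self, genes: tuple[str, ...]) -> "SignatureDefinition":
        keep = [i for i, g in enumerate(self.genes) if g in set(genes)]
        return SignatureDefinition(
            name=self.name,
            genes=tuple(self.genes[i] for i in keep),
            method=self.method,
            directions=tuple(int(self.resolved_directions[i]) for i in keep)
            if self.directions
            else (),
        )


@dataclass
class SignatureScores:
    """Per-sample scores plus the fraction of signature genes present."""

    name: str
    scores: pd.Series
    coverage: float
    missing_genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")
        if self.coverage > 0 and not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite when coverage > 0")


def score_signature(expr: pd.DataFrame, sig: SignatureDefinition) -> SignatureScores:
    """Score a signature on a log-scale gene x sample matrix.

    ``mean_z``: each present gene is z-scored across samples (population
    SD; zero-variance genes contribute 0), multiplied by its direction,
    and the per-gene values are averaged.  The result is invariant to
    per-gene affine rescaling of the input.  ``mean_log``: directed mean
    of the raw log values (not scale-free; kept for platform floors).
    """
    present = [g for g in sig.genes if g in expr.index]
    missing = tuple(g for g in sig.genes if g not in expr.index)
    if not present:
        raise ValueError(
            f"signature {sig.name!r} has zero coverage; missing genes: "
            + ", ".join(missing[:10])
        )
    dirs = sig.resolved_directions[[i for i, g in enumerate(sig.genes) if g in expr.index]]
    sub = expr.loc[present].to_numpy(dtype=float)
    if sig.method == "mean_z":
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        z = np.divide(sub - mu, sd, out=np.zeros_like(sub), where=sd > 0)
        vals = (dirs[:, None] * z).mean(axis=0)
    else:  # mean_log
        vals = (dirs[:, None] * sub).mean(axis=0)
    return SignatureScores(
        name=sig.name,
        scores=pd.Series(vals, index=expr.columns, name=sig.name),
        coverage=len(present) / len(sig.genes),
        missing_genes=missing,
    )


def classify_hot_cold(scores: SignatureScores | pd.Series, rule="median") -> pd.Series:
    """Dichotomize scores into hot (1) / cold (0).

    ``rule`` is ``"median"`` or ``("fixed", c)``.  The label is
    ``score > cutoff``; ties at the cutoff are assigned cold.
    """
    s = scores.scores if isinstance(scores, SignatureScores) else scores
    if rule == "median":
        if len(s) < 2:
            raise ValueError("median rule needs >= 2 samples")
        cutoff = float(np.median(s))
    elif isinstance(rule, tuple) and len(rule) == 2 and rule[0] == "fixed":
        cutoff = float(rule[1])
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return (s > cutoff).astype(int).rename("hot")


def make_negative_controls(
    gene_universe,
    size: int,
    n_controls: int,
    seed: int = 0,
    exclude: tuple[str, ...] | None = None,
) -> list[SignatureDefinition]:
    """Random gene-set signatures disjoint from the tri-axis genes.

    Used as specificity controls: a random gene set of the same size as
    the real signature should not survive platform perturbations the
    way the real, correlated program does.
    """
    if exclude is None:
        exclude = (FOCAL_GENE, CD274_GENE, *hot_gene_names())
    pool = [g for g in gene_universe if g not in set(exclude)]
    if len(pool) < size:
        raise ValueError("gene universe too small after exclusions")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_controls):
        genes = tuple(sorted(rng.choice(pool, size=size, replace=False)))
        out.append(SignatureDefinition(name=f"NegCtrl{i + 1}", genes=genes))
    return out


def default_hot_signature(n: int = 27) -> SignatureDefinition:
    """The synthetic stand-in for the 27-gene immune-hot signature."""
    return SignatureDefinition(name="HOT", genes=tuple(hot_gene_names(n)))


def load_signature_registry(path) -> dict[str, SignatureDefinition]:
    """Read a TSV registry with columns signature, gene, direction."""
    tab = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for name, grp in tab.groupby("signature", sort=False):
        out[name] = SignatureDefinition(
            name=name,
            genes=tuple(grp["gene"]),
            directions=tuple(int(d) for d in grp.get("direction", [1] * len(grp))),
        )
    return out


def write_signature_registry(sigs, path) -> None:
    rows = []
    for sig in sigs:
        for g, d in zip(sig.genes, sig.resolved_directions):
            rows.append({"signature": sig.name, "gene": g, "direction": int(d)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def bundled_registry() -> dict[str, SignatureDefinition]:
    """The registry shipped with the package (HOT + benchmark stand-ins)."""
    ref = resources.files("triaxis.data") / "synthetic_signatures.tsv"
    with resources.as_file(ref) as path:
        return load_signature_registry(path)
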