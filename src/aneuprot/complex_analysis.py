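"""Complex-level attenuation: partition, enrichment, and subunit summaries.

Duplicated-gene products are split by membership in a curated complex
catalog. Attenuated genes are tested for enrichment of complex subunits by
an upper-tail hypergeometric test against the background of detected
duplicated genes. Per-complex summaries pool each subunit's measurement in
the strain where its gene is duplicated; a complex counts as attenuated
when its subunit mean log2 ratio is <= 0.6 (a 1.5-fold rise instead of the
twofold expected from gene dosage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dosage_stats import AttenuationCallSet
from .io_tables import ComplexCatalog

#: a subunit (or complex mean) at or below this log2 ratio is attenuated
SUBUNIT_CUTOFF = 0.6


@dataclass
class EnrichmentResult:
    """Hypergeometric upper-tail enrichment of a gene set among attenuated."""

    k: int  # attenuated ∩ set
    n: int  # attenuated
    K: int  # set ∩ background
    N: int  # background
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError("inconsistent contingency counts")


@dataclass
class ComplexSummary:
    """Attenuation summary of one complex across datasets."""

    complex_id: str
    subunit_ratios: dict[str, dict[str, float]]  # dataset -> gene -> log2 ratio
    means: dict[str, float]  # dataset -> mean over subunits
    n_subunits: dict[str, int]
    attenuated_complex: bool
    attenuated_subunits: list[str] = field(default_factory=list)
    stable_subunits: list[str] = field(default_factory=list)


def enrichment_test(
    attenuated: set[str], target_set: set[str], background: set[str]
) -> EnrichmentResult:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N = background size, K = target-set genes in the background, n = number
    attenuated, k = attenuated genes in the target set.
    """
    if not background:
        raise ValueError("background must not be empty")
    if not attenuated <= background or not target_set <= set(background):
        raise ValueError("attenuated and target_set must be subsets of background")
    N = len(background)
    K = len(target_set & background)
    n = len(attenuated)
    k = len(attenuated & target_set)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(k=k, n=n, K=K, N=N, p_value=min(max(p, 0.0), 1.0))


def overlap_analysis(
    calls_a: AttenuationCallSet, calls_b: AttenuationCallSet
) -> dict:
    """Gene-level overlap of two attenuation call sets.

    A gene counts once even when measured in several strains. Returns the
    intersection, Jaccard index, and the fraction of each call set shared.
    """
    a = calls_a.attenuated_genes()
    b = calls_b.attenuated_genes()
    inter = a & b
    union = a | b
    return {
        "intersection": inter,
        "jaccard": len(inter) / len(union) if union else np.nan,
        "fraction_of_a": len(inter) / len(a) if a else np.nan,
        "fraction_of_b": len(inter) / len(b) if b else np.nan,
    }


def _gene_ratio(calls: AttenuationCallSet, gene: str) -> float:
    """A gene's duplicated-instance ratio; mean when duplicated in several strains."""
    sub = calls.calls.loc[calls.calls["gene"] == gene, "value"]
    return float(sub.mean())


def summarize_complexes(
    catalog: ComplexCatalog,
    datasets: Mapping[str, AttenuationCallSet],
    min_subunits: int = 3,
    require_all_datasets: bool = True,
    attenuation_datasets: Sequence[str] | None = None,
) -> list[ComplexSummary]:
    """Per-complex pooled duplicated-instance ratios and attenuation status.

    Only complexes with >= ``min_subunits`` quantified subunits in every
    dataset (or any one, when ``require_all_datasets=False``) are reported.
    ``attenuated_complex`` is true when the subunit mean is <= 0.6 in all
    designated datasets (default: every dataset). Subunit classification
    (attenuated vs stable, cutoff 0.6) uses the mean ratio across datasets.
    """
    if not catalog.complexes:
        raise ValueError("empty complex catalog")
    if attenuation_datasets is None:
        attenuation_datasets = list(datasets)
    per_dataset_values: dict[str, pd.DataFrame] = {
        name: calls.calls.groupby("gene")["value"].mean()
        for name, calls in datasets.items()
    }
    out: list[ComplexSummary] = []
    for cid, members in catalog.complexes.items():
        ratios: dict[str, dict[str, float]] = {}
        for name, per_gene in per_dataset_values.items():
            found = {g: float(per_gene[g]) for g in members if g in per_gene.index}
            ratios[name] = found
        counts = {name: len(v) for name, v in ratios.items()}
        ok = (all if require_all_datasets else any)(
            c >= min_subunits for c in counts.values()
        )
        if not ok:
            continue
        means = {
            name: (float(np.mean(list(v.values()))) if v else np.nan)
            for name, v in ratios.items()
        }
        attenuated_complex = all(
            np.isfinite(means[name]) and means[name] <= SUBUNIT_CUTOFF
            for name in attenuation_datasets
        )
        quantified = sorted({g for v in ratios.values() for g in v})
        per_gene_mean = {
            g: float(np.mean([v[g] for v in ratios.values() if g in v]))
            for g in quantified
        }
        attenuated_subunits = [g for g in quantified if per_gene_mean[g] <= SUBUNIT_CUTOFF]
        stable_subunits = [g for g in quantified if per_gene_mean[g] > SUBUNIT_CUTOFF]
        out.append(
            ComplexSummary(
                complex_id=cid,
                subunit_ratios=ratios,
                means=means,
                n_subunits=counts,
                attenuated_complex=attenuated_complex,
                attenuated_subunits=attenuated_subunits,
                stable_subunits=stable_subunits,
            )
        )
    return out


def complex_vs_noncomplex_test(
    ratios: Mapping[str, float] | pd.Series, complex_members: set[str]
) -> dict:
    """Welch's two-sided t test: complex-member vs non-member log2 ratios."""
    series = pd.Series(ratios, dtype=float).dropna()
    in_complex = series[series.index.isin(complex_members)]
    outside = series[~series.index.isin(complex_members)]
    if in_complex.empty or outside.empty:
        raise ValueError("both groups must be non-empty")
    t, p = stats.ttest_ind(in_complex, outside, equal_var=False)
    return {
        "mean_complex": float(in_complex.mean()),
        "mean_noncomplex": float(outside.mean()),
        "n_complex": int(in_complex.size),
        "n_noncomplex": int(outside.size),
        "t": float(t),
        "welch_p": float(p),
    }


def cross_condition_correlation(
    ratios_a: Mapping[str, float] | pd.Series,
    ratios_b: Mapping[str, float] | pd.Series,
    exclude: set[str] | None = None,
) -> dict:
    """Pearson r of per-gene subunit ratios between two conditions.

    ``exclude`` drops gene sets whose extreme, uniform attenuation would
    dominate the correlation (typically the ribosome and nucleosome).
    """
    a = pd.Series(ratios_a, dtype=float)
    b = pd.Series(ratios_b, dtype=float)
    shared = a.index.intersection(b.index)
    if exclude:
        shared = shared[~shared.isin(exclude)]
    paired = pd.concat([a[shared], b[shared]], axis=1, keys=["a", "b"]).dropna()
    if len(paired) < 3:
        raise ValueError("need >= 3 shared genes after exclusions")
    r, p = stats.pearsonr(paired["a"], paired["b"])
    return {"r": float(r), "p_value": float(p), "n": int(len(paired))}
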