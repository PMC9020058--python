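"""Network-defined cancer genes: survival stratification by subgraph content.

Given per-patient subgraphs (node sets) and overall-survival records, split
the cohort for each gene by whether the gene appears in a patient's
subgraph, compare the two survival curves with a log-rank test, and rank
genes by significance.  Genes that stratify survival this way are candidate
network-defined cancer genes: their effect is defined by their network
context rather than by marginal expression alone.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalRecord",
    "read_survival_table",
    "stratify_by_gene",
    "km_estimate",
    "KMEstimate",
    "logrank_test",
    "network_defined_genes",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in days and whether death was observed
    (False = censored)."""

    patient_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("follow-up time must be >= 0")


def read_survival_table(path) -> list[SurvivalRecord]:
    """TSV with columns patient_id, time, event (event coded 0/1)."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "time", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    return [
        SurvivalRecord(str(r.patient_id), float(r.time), bool(int(r.event)))
        for r in df.itertuples()
    ]


def stratify_by_gene(
    collection: Mapping[str, Iterable[str]], gene: str
) -> tuple[frozenset[str], frozenset[str]]:
    """Partition patients by whether their subgraph contains ``gene``."""
    with_gene = frozenset(p for p, nodes in collection.items() if gene in set(nodes))
    without = frozenset(collection) - with_gene
    return with_gene, without


class KMEstimate:
    """Product-limit survival curve; callable as S(t)."""

    def __init__(self, records: Sequence[SurvivalRecord]):
        fitter = KaplanMeierFitter()
        fitter.fit(
            [r.time for r in records],
            event_observed=[int(r.event) for r in records],
        )
        self._fitter = fitter

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        out = self._fitter.predict(t)
        if np.isscalar(t):
            return float(out)
        return np.asarray(out)

    @property
    def timeline(self) -> np.ndarray:
        return np.asarray(self._fitter.timeline)

    def to_frame(self) -> pd.DataFrame:
        return self._fitter.survival_function_


def km_estimate(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Kaplan-Meier estimator of the survival function (right-continuous,
    non-increasing, S(0) = 1)."""
    if not records:
        raise ValueError("no survival records")
    return KMEstimate(records)


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Unweighted two-sample log-rank test (1 df chi-square).

    Returns ``(chi_square, p_value)``.  When neither group has any observed
    event the statistic is degenerate; (0, 1) is returned with a log notice.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in group_a) and not any(r.event for r in group_b):
        logger.warning("log-rank test degenerate: no events in either group")
        return 0.0, 1.0
    res = _ll_logrank(
        [r.time for r in group_a],
        [r.time for r in group_b],
        event_observed_A=[int(r.event) for r in group_a],
        event_observed_B=[int(r.event) for r in group_b],
    )
    return float(res.test_statistic), float(res.p_value)


def network_defined_genes(
    collection: Mapping[str, Iterable[str]],
    survival: Sequence[SurvivalRecord],
    min_group_size: int = 3,
    alpha: float = 0.05,
    correction: str = "benjamini-hochberg",
) -> pd.DataFrame:
    """Rank genes by how strongly their subgraph membership stratifies
    survival.

    Every gene appearing in at least one patient's subgraph and splitting
    the cohort into strata of at least ``min_group_size`` patients each gets
    a log-rank p-value.  The table is sorted by (adjusted) p ascending, with
    raw p-values always reported alongside; genes passing ``alpha`` are
    flagged.  Returns an empty table when no gene qualifies.
    """
    if correction not in ("none", "benjamini-hochberg"):
        raise ValueError("correction must be 'none' or 'benjamini-hochberg'")
    by_patient = {r.patient_id: r for r in survival}
    missing = set(collection) - set(by_patient)
    if missing:
        raise ValueError(f"patients without survival records: {sorted(missing)[:5]}")

    genes = sorted({g for nodes in collection.values() for g in nodes})
    rows = []
    for gene in genes:
        with_gene, without = stratify_by_gene(collection, gene)
        if len(with_gene) < min_group_size or len(without) < min_group_size:
            continue
        chi2, p = logrank_test(
            [by_patient[p_] for p_ in sorted(with_gene)],
            [by_patient[p_] for p_ in sorted(without)],
        )
        rows.append(
            {
                "gene": gene,
                "n_with": len(with_gene),
                "n_without": len(without),
                "chi_square": chi2,
                "p": p,
            }
        )
    columns = ["gene", "n_with", "n_without", "chi_square", "p", "p_adjusted", "significant"]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    if correction == "benjamini-hochberg":
        df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_adjusted"] = df["p"]
    df["significant"] = df["p_adjusted"] <= alpha
    df = df.sort_values(["p_adjusted", "p", "gene"], kind="mergesort").reset_index(drop=True)
    return df[columns]
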