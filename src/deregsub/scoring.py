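"""Node-score constructors from omics summary tables.

All constructors return plain ``{node-id: value}`` dicts ready to attach to
a network.  Trinary scores take values in {-1, 0, +1}: significant
down-regulation, no call, significant up-regulation.  The consistency score
is the indicator of opposing promoter-methylation and transcription calls.

Differential statistics (e.g. DESeq2 fold changes and p-values) and
normalized methylation beta values are consumed as inputs, never computed
here.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "trinary_global_score",
    "personalized_log2fc",
    "trinary_personalized_score",
    "call_dmps",
    "gene_methylation_score",
    "consistency_score",
    "absolute_score",
    "read_differential_table",
    "read_matrix",
    "read_probe_gene_map",
]


def read_differential_table(path) -> pd.DataFrame:
    """TSV with columns gene, log2_fold_change, p_value (header required)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2_fold_change", "p_value"}
    if not required <= set(df.columns):
        raise ValueError(f"differential table needs columns {sorted(required)}")
    if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
        raise ValueError("p_value outside [0, 1]")
    return df.set_index("gene")


def read_matrix(path) -> pd.DataFrame:
    """Feature x sample TSV matrix with the feature id in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_probe_gene_map(path) -> dict[str, frozenset[str]]:
    """Two-column TSV probe<TAB>gene; probes may map to several genes."""
    mapping: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"])
    for probe, gene in zip(df["probe"], df["gene"]):
        mapping.setdefault(str(probe), set()).add(str(gene))
    return {k: frozenset(v) for k, v in mapping.items()}


def trinary_global_score(
    table: pd.DataFrame, fc_cut: float = 2.0, p_cut: float = 0.05
) -> dict[str, int]:
    """Cohort-level trinary call per gene from a differential table.

    +1 when log2 fold change exceeds ``fc_cut`` at p below ``p_cut``,
    -1 when it falls below ``-fc_cut`` at p below ``p_cut``, 0 otherwise.
    Strict inequalities throughout.
    """
    out: dict[str, int] = {}
    for gene, row in table.iterrows():
        fc, p = float(row["log2_fold_change"]), float(row["p_value"])
        if fc > fc_cut and p < p_cut:
            out[str(gene)] = 1
        elif fc < -fc_cut and p < p_cut:
            out[str(gene)] = -1
        else:
            out[str(gene)] = 0
    return out


def personalized_log2fc(
    expression: pd.DataFrame,
    sample_group: Mapping[str, str],
    tumor_sample: str,
    pseudocount: float = 1.0,
) -> dict[str, float]:
    """Per-gene log2 of one tumor sample against the control-sample mean.

    The pseudocount is added to both the tumor value and the control mean
    before taking the log, so zero-expression genes score 0 rather than
    diverging.
    """
    if tumor_sample not in expression.columns:
        raise ValueError(f"sample {tumor_sample!r} not in the expression matrix")
    controls = [c for c in expression.columns if sample_group.get(c) == "control"]
    if not controls:
        raise ValueError("at least one control sample is required")
    ctrl_mean = expression[controls].mean(axis=1)
    ratio = (expression[tumor_sample] + pseudocount) / (ctrl_mean + pseudocount)
    return {str(g): float(v) for g, v in np.log2(ratio).items()}


def trinary_personalized_score(
    fold: Mapping[str, float], cut: float = 2.0
) -> dict[str, int]:
    """Trinary call on personalized log2 fold changes (strict inequalities)."""
    return {
        g: (1 if f > cut else (-1 if f < -cut else 0)) for g, f in fold.items()
    }


def call_dmps(
    beta: pd.DataFrame,
    sample_group: Mapping[str, str],
    delta: float = 0.2,
) -> dict[str, int]:
    """Signed differentially-methylated-probe calls.

    Per probe: +1 when the median tumor beta exceeds the median control beta
    by more than ``delta``, -1 when it falls short by more than ``delta``,
    0 otherwise.
    """
    if ((beta < 0) | (beta > 1)).any().any():
        raise ValueError("beta values must lie in [0, 1]")
    tumors = [c for c in beta.columns if sample_group.get(c) == "tumor"]
    controls = [c for c in beta.columns if sample_group.get(c) == "control"]
    if not tumors or not controls:
        raise ValueError("need at least one tumor and one control sample")
    diff = beta[tumors].median(axis=1) - beta[controls].median(axis=1)
    return {
        str(p): (1 if d > delta else (-1 if d < -delta else 0))
        for p, d in diff.items()
    }


def gene_methylation_score(
    dmp_calls: Mapping[str, int],
    probe_gene_map: Mapping[str, Iterable[str]],
) -> dict[str, int]:
    """Promoter-methylation gene score from probe calls.

    A gene is +1 when at least one mapped probe is called up and none down,
    -1 in the mirrored case, and 0 otherwise — including conflicting calls
    and genes with no mapped probe.
    """
    calls_per_gene: dict[str, list[int]] = {}
    for probe, genes in probe_gene_map.items():
        call = dmp_calls.get(probe, 0)
        for g in genes:
            calls_per_gene.setdefault(str(g), []).append(call)
    out: dict[str, int] = {}
    for g, calls in calls_per_gene.items():
        has_up = any(c == 1 for c in calls)
        has_down = any(c == -1 for c in calls)
        out[g] = 1 if (has_up and not has_down) else (-1 if (has_down and not has_up) else 0)
    return out


def consistency_score(
    trinary: Mapping[str, int], methyl: Mapping[str, int]
) -> dict[str, int]:
    """Indicator of opposing transcription and promoter-methylation calls:
    1 when the two trinary calls have strictly negative product, else 0.
    Genes missing from either input default to a 0 call."""
    for name, m in (("trinary", trinary), ("methyl", methyl)):
        bad = {g: v for g, v in m.items() if v not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"{name} score not valued in {{-1,0,1}}: {bad}")
    genes = set(trinary) | set(methyl)
    return {
        g: int(trinary.get(g, 0) * methyl.get(g, 0) < 0) for g in genes
    }


def absolute_score(score: Mapping[str, float]) -> dict[str, float]:
    """Element-wise absolute value of a node score."""
    return {g: abs(v) for g, v in score.items()}
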