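"""Expression summarization and qRT-PCR relative quantification.

FPKM matrices are held as pandas DataFrames (genes x samples); the heatmap
transform is log2(FPKM + pseudo-count). Relative qPCR expression uses the
Livak 2^-DDCt method: per condition, the target gene's cycle threshold is
normalized against a reference gene (DCt); the treated-minus-control
difference of mean DCt is DDCt and fold change is 2^-DDCt. Significance is
a Welch two-sample test on replicate DCt values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["gene", "condition", "replicate", "ct"]


def log2_heatmap_matrix(m: pd.DataFrame, pseudo: float = 1.0) -> pd.DataFrame:
    """log2(value + pseudo) transform; NA preserved, order preserved."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    values = m.to_numpy(dtype=float)
    if np.nanmin(values) < 0:
        raise ValueError("FPKM values must be non-negative")
    return pd.DataFrame(np.log2(values + pseudo), index=m.index, columns=m.columns)


@dataclass
class FoldChangeResult:
    """2^-DDCt quantification of one gene (treated vs control)."""

    gene_id: str
    ddct: float
    fold: float
    spread: float  # SD of replicate DCt differences across conditions
    p_value: float | None
    significant: bool | None

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold change must be positive")


def _validate_ct(t: pd.DataFrame, reference_gene: str, control: str,
                 treated: str) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    for cond in (control, treated):
        ref = t[(t.gene == reference_gene) & (t.condition == cond)]
        if ref.empty:
            raise ValueError(f"reference gene {reference_gene!r} missing in "
                             f"condition {cond!r}")
    return t


def delta_ct(t: pd.DataFrame, reference_gene: str, condition: str,
             gene: str) -> np.ndarray:
    """Replicate-paired DCt = Ct(gene) - Ct(reference) for one condition."""
    sel = t[t.condition == condition]
    target = sel[sel.gene == gene].set_index("replicate")["ct"]
    ref = sel[sel.gene == reference_gene].set_index("replicate")["ct"]
    shared = sorted(set(target.index) & set(ref.index))
    if not shared:
        raise ValueError(f"no paired replicates for {gene} in {condition}")
    return (target.loc[shared] - ref.loc[shared]).to_numpy(dtype=float)


def welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch test; identical zero-variance groups give p = 1."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    if np.std(a) == 0 and np.std(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def ddct_quantify(
    t: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
    treated_condition: str,
    alpha: float = 0.05,
) -> list[FoldChangeResult]:
    """2^-DDCt fold changes for every non-reference gene in the table.

    DDCt = mean(DCt_treated) - mean(DCt_control); fold = 2^-DDCt. A Welch
    test on the replicate DCt values supplies the p-value when both
    conditions have >= 2 replicates.
    """
    _validate_ct(t, reference_gene, control_condition, treated_condition)
    out = []
    for gene in sorted(set(t.gene)):
        if gene == reference_gene:
            continue
        d_ctl = delta_ct(t, reference_gene, control_condition, gene)
        d_trt = delta_ct(t, reference_gene, treated_condition, gene)
        ddct = float(np.mean(d_trt) - np.mean(d_ctl))
        if len(d_ctl) >= 2 and len(d_trt) >= 2:
            p = welch_p(d_trt, d_ctl)
            significant = p < alpha
        else:
            p = significant = None
        out.append(
            FoldChangeResult(
                gene_id=gene,
                ddct=ddct,
                fold=float(2.0 ** (-ddct)),
                spread=float(np.std(np.concatenate([d_ctl - d_ctl.mean(),
                                                    d_trt - d_trt.mean()]))),
                p_value=p,
                significant=significant,
            )
        )
    return out


def significance_test(
    t: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
    treated_condition: str,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Welch p-values on replicate DCt values per gene."""
    _validate_ct(t, reference_gene, control_condition, treated_condition)
    out = {}
    for gene in sorted(set(t.gene)):
        if gene == reference_gene:
            continue
        a = delta_ct(t, reference_gene, treated_condition, gene)
        b = delta_ct(t, reference_gene, control_condition, gene)
        out[gene] = welch_p(a, b)
    return out


def read_fpkm(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_ct(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
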