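"""Differential-expression gene signatures from a two-group contrast.

Per gene: Welch two-sample t on log-scale values, log2 fold change as the
difference of group means (log-scale data assumed), Benjamini-Hochberg
adjustment across genes. Signature members are the genes passing both the
FDR and fold-change thresholds. A moderated-t signature computed elsewhere
can be imported through the GMT interface instead.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, GeneSet, ValidationError

logger = logging.getLogger("netmra")


@dataclass
class GeneSignature:
    """Per-gene DE statistics plus the selected member set."""

    table: pd.DataFrame  # index gene; columns statistic, log2_fc, p, p_adj, direction
    alpha: float
    lfc_min: float

    @property
    def members(self) -> list[str]:
        sel = (self.table["p_adj"] < self.alpha) & (self.table["log2_fc"].abs() >= self.lfc_min)
        return list(self.table.index[sel])

    def gene_set(self, name: str = "signature") -> GeneSet:
        if not self.members:
            raise ValidationError("signature has no members at the configured thresholds")
        return GeneSet(name, f"DE signature (alpha={self.alpha}, lfc>={self.lfc_min})",
                       self.members)


def compute_de_signature(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> GeneSignature:
    """Welch-t differential expression of B versus A on the shared gene space.

    log2_fc = mean(B) - mean(A); direction "up" means higher in B. Genes
    with zero variance in both groups get p=0 if the means differ (decisive
    degenerate case, logged) and p=1 otherwise.
    """
    if expr_a.n_samples < 2 or expr_b.n_samples < 2:
        raise ValidationError("need at least 2 samples per group")
    shared = [g for g in expr_a.gene_ids if g in expr_b]
    if not shared:
        raise ValidationError("the two matrices share no genes")
    dropped = (expr_a.n_genes - len(shared)) + (expr_b.n_genes - len(shared))
    if dropped:
        logger.warning("dropping %d genes outside the shared gene space", dropped)

    a = np.vstack([expr_a.row(g) for g in shared])
    b = np.vstack([expr_b.row(g) for g in shared])
    lfc = b.mean(axis=1) - a.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.warning("%d genes with zero variance in both groups", int(degenerate.sum()))
        p = np.where(degenerate, np.where(lfc != 0, 0.0, 1.0), p)
        t = np.where(np.isfinite(t), t, np.where(lfc > 0, np.inf, np.where(lfc < 0, -np.inf, 0.0)))
    p_adj = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "statistic": t,
            "log2_fc": lfc,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(lfc >= 0, "up", "down"),
        },
        index=pd.Index(shared, name="gene"),
    )
    return GeneSignature(table, alpha=alpha, lfc_min=lfc_min)
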