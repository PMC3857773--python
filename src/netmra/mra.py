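"""Master regulator analysis (MRA).

Each regulon is scored for enrichment with a query signature by the
one-sided hypergeometric test on the regulon/signature overlap within a
stated gene universe, with BH correction across regulons. Master
regulators found independently in two disease networks are intersected
(consensus), then filtered for tissue specificity (TFs also significant in
a control-tissue network queried with the same signature) and for
nonspecific proliferation (TFs significant against a proliferation
signature in either disease network).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import GeneSet, ValidationError

logger = logging.getLogger("netmra")


@dataclass
class MRAResult:
    """Enrichment of one regulon with the query signature."""

    tf: str
    regulon_size: int
    signature_size: int
    overlap: int
    universe_size: int
    p: float
    p_adj: float = float("nan")


@dataclass
class ConsensusReport:
    mrs_network1: set[str]
    mrs_network2: set[str]
    consensus: set[str]
    control_mrs: set[str] = field(default_factory=set)
    proliferation_mrs: set[str] = field(default_factory=set)
    final: set[str] = field(default_factory=set)
    provenance: list[str] = field(default_factory=list)


def hypergeom_upper_tail(k: int, universe: int, signature: int, regulon: int) -> float:
    """P(X >= k) for the overlap of a random regulon-sized draw with the
    signature inside the universe."""
    return float(hypergeom.sf(k - 1, universe, signature, regulon))


def mra_enrichment(
    regulons: list[GeneSet],
    signature: GeneSet,
    universe: set[str],
    alpha: float = 0.05,
) -> list[MRAResult]:
    """Score every regulon against the signature; BH across regulons.

    Members outside the universe are dropped with a warning — enrichment is
    conditional on the genes the network could measure.
    """
    universe = set(universe)
    sig = signature.as_set() & universe
    n_dropped = len(signature.as_set()) - len(sig)
    if n_dropped:
        logger.warning("dropped %d signature genes outside the universe", n_dropped)
    if not sig:
        raise ValidationError("signature is empty after universe intersection")

    results: list[MRAResult] = []
    for reg in regulons:
        members = reg.as_set() & universe
        if len(members) < len(reg):
            logger.warning("dropped %d members of regulon %s outside the universe",
                           len(reg) - len(members), reg.name)
        k = len(members & sig)
        p = hypergeom_upper_tail(k, len(universe), len(sig), len(members))
        results.append(MRAResult(reg.name, len(members), len(sig), k, len(universe), p))
    if results:
        p_adj = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, pa in zip(results, p_adj):
            r.p_adj = float(pa)
    return results


def significant_mrs(results: list[MRAResult], alpha: float = 0.05) -> set[str]:
    return {r.tf for r in results if r.p_adj < alpha}


def consensus_mrs(
    result_a: list[MRAResult], result_b: list[MRAResult], alpha: float = 0.05
) -> set[str]:
    """TFs significant (BH-adjusted p < alpha) in both networks."""
    return significant_mrs(result_a, alpha) & significant_mrs(result_b, alpha)


def specificity_filter(
    consensus: set[str],
    control_result: list[MRAResult],
    prolif_a: list[MRAResult],
    prolif_b: list[MRAResult],
    alpha: float = 0.05,
    mrs_network1: set[str] | None = None,
    mrs_network2: set[str] | None = None,
) -> ConsensusReport:
    """Remove consensus TFs that are also master regulators of the same
    signature in the control-tissue network, or of the proliferation
    signature in either disease network. Every exclusion is logged with
    its reason."""
    control = significant_mrs(control_result, alpha)
    prolif = significant_mrs(prolif_a, alpha) | significant_mrs(prolif_b, alpha)
    provenance: list[str] = []
    final: set[str] = set()
    for tf in sorted(consensus):
        if tf in control:
            provenance.append(f"{tf}: excluded (significant in control-tissue network)")
        elif tf in prolif:
            provenance.append(f"{tf}: excluded (significant for proliferation signature)")
        else:
            provenance.append(f"{tf}: retained")
            final.add(tf)
    return ConsensusReport(
        mrs_network1=set(mrs_network1 or set()),
        mrs_network2=set(mrs_network2 or set()),
        consensus=set(consensus),
        control_mrs=control,
        proliferation_mrs=prolif,
        final=final,
        provenance=provenance,
    )


def jaccard(a: set[str], b: set[str]) -> float:
    """|a & b| / |a | b|; two empty sets give 0 by convention (logged)."""
    union = set(a) | set(b)
    if not union:
        logger.warning("jaccard of two empty sets: returning 0 by convention")
        return 0.0
    return len(set(a) & set(b)) / len(union)


def regulon_overlap_table(
    regulons_a: list[GeneSet], regulons_b: list[GeneSet]
) -> pd.DataFrame:
    """Cross-network regulon agreement, one row per TF present in both
    networks: sizes, overlap count, overlap as percent of the smaller
    regulon, and Jaccard similarity."""
    by_a = {r.name: r.as_set() for r in regulons_a}
    by_b = {r.name: r.as_set() for r in regulons_b}
    rows = []
    for tf in sorted(by_a):
        if tf not in by_b:
            logger.info("TF %s absent from the second network: no overlap row", tf)
            continue
        a, b = by_a[tf], by_b[tf]
        k = len(a & b)
        rows.append(
            {
                "tf": tf,
                "size_a": len(a),
                "size_b": len(b),
                "overlap_count": k,
                "overlap_pct": 100.0 * k / min(len(a), len(b)) if a and b else 0.0,
                "jaccard": jaccard(a, b),
            }
        )
    return pd.DataFrame(rows, columns=["tf", "size_a", "size_b", "overlap_count",
                                       "overlap_pct", "jaccard"])


def results_to_frame(results: list[MRAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tf": r.tf,
                "regulon_size": r.regulon_size,
                "signature_size": r.signature_size,
                "overlap": r.overlap,
                "universe_size": r.universe_size,
                "p": r.p,
                "p_adj": r.p_adj,
            }
            for r in results
        ]
    )
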