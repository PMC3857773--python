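"""Ground-truthed synthetic data with the statistical structure the
analysis assumes.

The generative model is deliberately minimal: regulator expression is
i.i.d. standard normal across samples and each target gene is a signed
linear (optionally quadratic) function of exactly one regulator plus
Gaussian noise. That is the weakest structure mutual-information inference
must detect; the quadratic option produces non-monotone dependence that
rank correlation misses but MI does not. Background genes are pure noise.

Everything is driven by ``numpy.random.default_rng`` seeded explicitly:
the same seed gives byte-identical output on any platform.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ExpressionMatrix, GeneSet, MotifModel, SurvivalTable, ValidationError


@dataclass
class SimulationConfig:
    """Knobs of the expression simulator.

    Defaults describe the benchmark condition used throughout the test
    suite: 20 regulators with 30 targets each, 200 samples, signal slope 1
    against noise sd 0.25 (a strong, realistically detectable regulon).
    """

    n_tfs: int = 20
    n_targets: int = 600
    n_background_genes: int = 200
    regulon_size_range: tuple[int, int] = (30, 30)
    n_samples: int = 200
    noise_sd: float = 0.25
    signal_slope: float = 1.0
    nonlinearity: str = "linear"  # linear | quadratic | none
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("SimulationConfig.seed is mandatory (no implicit entropy)")
        for name in ("n_tfs", "n_targets", "n_background_genes", "n_samples"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        lo, hi = self.regulon_size_range
        if lo < 0 or hi < lo:
            raise ValidationError("regulon_size_range must be 0 <= lo <= hi")
        if self.nonlinearity not in ("linear", "quadratic", "none"):
            raise ValidationError(f"unknown nonlinearity {self.nonlinearity!r}")


@dataclass
class NetworkGroundTruth:
    """Planted regulatory structure behind a simulated expression matrix."""

    tf_ids: list[str]
    target_ids: list[str]
    background_ids: list[str]
    edges: list[tuple[str, str, int, float]]  # (tf, target, sign, slope)
    regulons: dict[str, set[str]]
    driver_tfs: list[str] = field(default_factory=list)
    differential_genes: set[str] = field(default_factory=set)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(tf, tgt) for tf, tgt, _, _ in self.edges}


def _plant_structure(cfg: SimulationConfig, rng: np.random.Generator) -> NetworkGroundTruth:
    lo, hi = cfg.regulon_size_range
    if cfg.n_tfs > 0 and lo > cfg.n_targets:
        raise ValidationError("regulon_size_range exceeds n_targets")
    tf_ids = [f"TF{i:03d}" for i in range(cfg.n_tfs)]
    target_ids = [f"G{i:04d}" for i in range(cfg.n_targets)]
    background_ids = [f"BG{i:04d}" for i in range(cfg.n_background_genes)]

    edges: list[tuple[str, str, int, float]] = []
    regulons: dict[str, set[str]] = {tf: set() for tf in tf_ids}
    # random target-to-TF assignment: two independently planted structures
    # over the same id space must not share regulons by construction
    shuffled = [target_ids[i] for i in rng.permutation(cfg.n_targets)]
    cursor = 0
    for tf in tf_ids:
        size = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        size = min(size, cfg.n_targets - cursor)
        for tgt in shuffled[cursor : cursor + size]:
            sign = 1 if rng.random() < 0.5 else -1
            edges.append((tf, tgt, sign, cfg.signal_slope))
            regulons[tf].add(tgt)
        cursor += size
    return NetworkGroundTruth(tf_ids, target_ids, background_ids, edges, regulons)


def _expression_from_truth(
    cfg: SimulationConfig,
    truth: NetworkGroundTruth,
    rng: np.random.Generator,
    tf_shift: dict[str, float] | None = None,
) -> ExpressionMatrix:
    """Sample one cohort from a planted structure; ``tf_shift`` moves the
    mean of selected regulators (condition effects propagate through the
    generative slopes)."""
    n = cfg.n_samples
    tf_expr = {tf: rng.standard_normal(n) for tf in truth.tf_ids}
    if tf_shift:
        for tf, delta in tf_shift.items():
            tf_expr[tf] = tf_expr[tf] + delta

    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    for tf in truth.tf_ids:
        gene_ids.append(tf)
        rows.append(tf_expr[tf])
    regulator_of = {tgt: (tf, sign, slope) for tf, tgt, sign, slope in truth.edges}
    for tgt in truth.target_ids:
        gene_ids.append(tgt)
        if tgt in regulator_of:
            tf, sign, slope = regulator_of[tgt]
            x = tf_expr[tf]
            if cfg.nonlinearity == "quadratic":
                signal = sign * slope * x**2
            elif cfg.nonlinearity == "none":
                signal = 0.0
            else:
                signal = sign * slope * x
            rows.append(signal + rng.normal(0.0, cfg.noise_sd, n))
        else:
            rows.append(rng.normal(0.0, cfg.noise_sd, n))
    for bg in truth.background_ids:
        gene_ids.append(bg)
        rows.append(rng.standard_normal(n))

    samples = [f"S{i:03d}" for i in range(n)]
    values = np.vstack(rows) if rows else np.empty((0, n))
    return ExpressionMatrix(gene_ids, samples, values)


def simulate_network_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, NetworkGroundTruth]:
    """One cohort with planted TF->target regulons plus background noise."""
    rng = np.random.default_rng(cfg.seed)
    truth = _plant_structure(cfg, rng)
    expr = _expression_from_truth(cfg, truth, rng)
    return expr, truth


def simulate_replicate_cohorts(
    cfg: SimulationConfig, n_cohorts: int
) -> tuple[list[ExpressionMatrix], NetworkGroundTruth]:
    """Several cohorts sampled independently from one planted structure —
    the stand-in for profiling the same disease on different patient
    series. Structure planting consumes the RNG stream before any sampling,
    so two configs with the same seed share the same ground truth."""
    rng = np.random.default_rng(cfg.seed)
    truth = _plant_structure(cfg, rng)
    cohorts = [_expression_from_truth(cfg, truth, rng) for _ in range(n_cohorts)]
    return cohorts, truth


def simulate_two_group_expression(
    cfg: SimulationConfig, driver_tfs: list[str], effect_size: float
) -> tuple[ExpressionMatrix, ExpressionMatrix, NetworkGroundTruth]:
    """Two cohorts from one planted structure; group B shifts each driver
    regulator's mean by ``effect_size`` (in sd units), which propagates to
    its regulon through the generative slopes. The truth records which genes
    are differential between the groups."""
    rng = np.random.default_rng(cfg.seed)
    truth = _plant_structure(cfg, rng)
    unknown = [tf for tf in driver_tfs if tf not in truth.regulons]
    if unknown:
        raise ValidationError(f"unknown driver tf ids: {unknown}")
    truth.driver_tfs = list(driver_tfs)
    if effect_size != 0:
        diff = set(driver_tfs)
        for tf in driver_tfs:
            # linear targets shift by sign*slope*effect; quadratic ones also
            # move (E[(x+d)^2] != E[x^2]) so they count as differential too
            if cfg.nonlinearity != "none":
                diff |= truth.regulons[tf]
        truth.differential_genes = diff

    expr_a = _expression_from_truth(cfg, truth, rng)
    shift = {tf: effect_size for tf in driver_tfs}
    expr_b = _expression_from_truth(cfg, truth, rng, tf_shift=shift)
    return expr_a, expr_b, truth


def simulate_chain_expression(
    n_chains: int, n_samples: int, noise_sd: float, slope: float, seed: int
) -> tuple[ExpressionMatrix, list[tuple[str, str, str]]]:
    """Planted regulatory chains A -> B -> C (B = slope*A + noise,
    C = slope*B + noise) with A and B acting as regulators. The indirect
    A-C association is what data-processing-inequality pruning must remove.

    Returns the matrix and the list of (A, B, C) gene-id triples; the TF
    list for inference is all A and B genes.
    """
    rng = np.random.default_rng(seed)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    chains: list[tuple[str, str, str]] = []
    for i in range(n_chains):
        a = rng.standard_normal(n_samples)
        b = slope * a + rng.normal(0.0, noise_sd, n_samples)
        c = slope * b + rng.normal(0.0, noise_sd, n_samples)
        ida, idb, idc = f"A{i:03d}", f"B{i:03d}", f"C{i:03d}"
        gene_ids += [ida, idb, idc]
        rows += [a, b, c]
        chains.append((ida, idb, idc))
    samples = [f"S{i:03d}" for i in range(n_samples)]
    return ExpressionMatrix(gene_ids, samples, np.vstack(rows)), chains


def simulate_flank_sequences(
    gene_ids: list[str],
    motif: MotifModel,
    hit_rate_in: float,
    hit_rate_out: float,
    flank_len: int,
    regulon: GeneSet,
    seed: int,
    gc_fraction: float = 0.5,
) -> tuple[dict[str, str], set[str]]:
    """Random flanking sequences (length 2*flank_len, i.i.d. background) with
    the motif consensus planted at elevated rate in regulon genes.

    Returns the FASTA mapping and the set of genes that received a planted
    occurrence. Planting inserts one consensus word at a uniform random
    position on a uniform random strand.
    """
    if not (0 <= hit_rate_in <= 1 and 0 <= hit_rate_out <= 1):
        raise ValidationError("hit rates must lie in [0, 1]")
    if flank_len < motif.length:
        raise ValidationError("flank_len must be >= motif length")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    consensus = motif.consensus()
    rc = consensus.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    members = regulon.as_set()
    seq_len = 2 * flank_len

    sequences: dict[str, str] = {}
    planted: set[str] = set()
    for gene in gene_ids:
        seq = list(bases[rng.choice(4, size=seq_len, p=p)])
        rate = hit_rate_in if gene in members else hit_rate_out
        if rate > 0 and rng.random() < rate:
            pos = int(rng.integers(0, seq_len - motif.length + 1))
            word = consensus if rng.random() < 0.5 else rc
            seq[pos : pos + motif.length] = list(word)
            planted.add(gene)
        sequences[gene] = "".join(seq)
    return sequences, planted


def simulate_survival(
    n: int, beta: float, baseline_rate: float, censor_rate: float, seed: int
) -> tuple[SurvivalTable, float]:
    """Exponential proportional-hazards cohort: covariate x ~ N(0,1), event
    time ~ Exp(baseline_rate * exp(beta*x)), independent exponential
    censoring. Returns the table and the true log hazard ratio."""
    if n < 2:
        raise ValidationError("need at least 2 subjects")
    if baseline_rate <= 0:
        raise ValidationError("baseline_rate must be > 0")
    if censor_rate < 0:
        raise ValidationError("censor_rate must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    event_time = rng.exponential(1.0 / (baseline_rate * np.exp(beta * x)))
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    ids = [f"P{i:04d}" for i in range(n)]
    return SurvivalTable(ids, time, event, x), beta


# E-box (CACGTG-class) count matrix used as the default planted motif: a
# sharply informative core with soft shoulders, the shape of bHLH-family
# binding models.
EBOX_COUNTS = np.array(
    [
        #  C    A    C    G    T    G
        [10, 85,  2,  2,  3,  5],   # A
        [75,  5, 90,  3,  2,  5],   # C
        [ 5,  5,  4, 90,  5, 85],   # G
        [10,  5,  4,  5, 90,  5],   # T
    ],
    dtype=float,
)


def ebox_motif(motif_id: str = "EBOX") -> MotifModel:
    """The default CACGTG-consensus motif model planted by the generators."""
    return MotifModel(motif_id, EBOX_COUNTS.copy())


def write_synthetic_study(
    out_dir,
    seed: int,
    cfg: SimulationConfig | None = None,
    n_contrast_samples: int = 30,
    effect_size: float = 2.0,
    flank_len: int = 300,
    hit_rate_in: float = 0.8,
    hit_rate_out: float = 0.1,
    survival_n: int = 200,
    survival_beta: float = float(np.log(2)),
) -> tuple[dict, NetworkGroundTruth]:
    """Emit a complete synthetic study to ``out_dir`` and return a pipeline
    config dict pointing at the files, plus the ground truth.

    The study mirrors the real analysis layout: two disease cohorts sampled
    from one planted regulatory structure, an independent control-tissue
    cohort (different structure, same TF ids), a two-group contrast whose
    group B shifts one driver TF, a proliferation signature (the truth
    regulon of a designated non-driver TF), E-box motif flanks planted at
    elevated rate in the driver regulon, and an exponential
    proportional-hazards survival cohort.
    """
    from pathlib import Path

    from . import io as nio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg is None:
        cfg = SimulationConfig(
            n_tfs=8, n_targets=160, n_background_genes=60,
            regulon_size_range=(20, 20), n_samples=120, seed=seed,
        )
    driver = "TF000"
    prolif_tf = f"TF{cfg.n_tfs - 1:03d}"

    cohorts, truth = simulate_replicate_cohorts(cfg, 2)
    truth.driver_tfs = [driver]
    nio.write_expression_matrix(cohorts[0], out / "expr_disease_a.tsv")
    nio.write_expression_matrix(cohorts[1], out / "expr_disease_b.tsv")

    control_cfg = replace(cfg, seed=seed + 101)
    control_expr, _ = simulate_network_expression(control_cfg)
    nio.write_expression_matrix(control_expr, out / "expr_control.tsv")

    contrast_cfg = replace(cfg, n_samples=n_contrast_samples)
    expr_a, expr_b, _ = simulate_two_group_expression(contrast_cfg, [driver], effect_size)
    nio.write_expression_matrix(expr_a, out / "contrast_primary.tsv")
    nio.write_expression_matrix(expr_b, out / "contrast_metastasis.tsv")

    nio.write_gene_list(truth.tf_ids, out / "tfs.txt")
    nio.write_gene_sets_gmt(
        [GeneSet(tf, f"true regulon of {tf}", sorted(m)) for tf, m in truth.regulons.items() if m],
        out / "true_regulons.gmt",
    )
    prolif_members = sorted(truth.regulons[prolif_tf])
    nio.write_gene_sets_gmt(
        [GeneSet("proliferation", "synthetic proliferation signature", prolif_members)],
        out / "proliferation.gmt",
    )

    motif = ebox_motif()
    nio.write_pfm_jaspar(motif, out / "ebox.pfm")
    gene_ids = cohorts[0].gene_ids
    driver_regulon = GeneSet(driver, "driver regulon", sorted(truth.regulons[driver]))
    flanks, planted = simulate_flank_sequences(
        gene_ids, motif, hit_rate_in, hit_rate_out, flank_len, driver_regulon,
        seed=seed + 202,
    )
    nio.write_fasta(flanks, out / "flanks.fa")

    table, _ = simulate_survival(survival_n, survival_beta, baseline_rate=0.1,
                                 censor_rate=0.02, seed=seed + 303)
    nio.write_survival_table(table, out / "survival.tsv")

    truth_record = {
        "driver_tfs": [driver],
        "proliferation_tf": prolif_tf,
        "regulons": {tf: sorted(m) for tf, m in truth.regulons.items()},
        "motif_planted_genes": sorted(planted),
        "survival_beta": survival_beta,
    }
    import json

    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_record, fh, indent=2)

    config = {
        "seed": seed,
        "expr_disease_a": str(out / "expr_disease_a.tsv"),
        "expr_disease_b": str(out / "expr_disease_b.tsv"),
        "expr_control": str(out / "expr_control.tsv"),
        "tf_list": str(out / "tfs.txt"),
        "contrast_a": str(out / "contrast_primary.tsv"),
        "contrast_b": str(out / "contrast_metastasis.tsv"),
        "proliferation_signature_gmt": str(out / "proliferation.gmt"),
        "pfm": str(out / "ebox.pfm"),
        "flanks_fasta": str(out / "flanks.fa"),
        "survival_tables": [str(out / "survival.tsv")],
    }
    with open(out / "config.json", "w", encoding="utf-8") as fh:
        json.dump(config, fh, indent=2)
    return config, truth
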