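"""Synthetic single-cell counts with the structure the pipeline assumes.

Counts are negative-binomial draws around a fixed gene-level expression
profile, thinned per cell so that the cohort hits the capture profile of
the platform: nanobiopsies express ~497 protein-coding genes on average
with ~23.4% mitochondrial counts, whole-cell lysates ~1100 genes with
~7.5%.  Proneural (PN) and mesenchymal (MES) phenotypes are planted as
multiplicative shifts of two 50-gene modules, and paired day-1 / day-4
cohorts flip phenotype with treatment-dependent switch probabilities
(0.7 untreated, 0.11 treated), returning the planted truth for oracle
testing.

This generator exists to make the pipeline testable without sequencing
data; it models capture statistics, not library chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq

from .sicm_model import InvalidParameterError
from .transcriptomics import CountsMatrix

__all__ = [
    "GeneratorConfig",
    "CAPTURE_PROFILES",
    "gen_counts",
    "gen_paired_cohort",
    "gene_sets",
    "fixture_toy_counts",
    "FIXTURE_PASS_CELLS",
    "FIXTURE_KEPT_GENES",
    "FIXTURE_THRESHOLDS",
]

# Cohort-level capture targets: mean expressed protein-coding genes and
# mean % mitochondrial counts per profile.
CAPTURE_PROFILES = {
    "nanobiopsy": {"target_expressed_genes": 497.0, "target_mito_pct": 23.4},
    "whole_cell": {"target_expressed_genes": 1100.0, "target_mito_pct": 7.5},
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-cohort parameters.

    ``dispersion`` is the negative-binomial overdispersion alpha
    (variance = m + alpha m^2).  ``effect_size`` is the natural-log fold
    change applied to a phenotype's module genes in cells of that
    phenotype.  ``cell_efficiency_sd`` is the log-normal sd of the
    per-cell capture depth around the calibrated profile depth, and
    ``mito_noise_sd`` the log-normal sd of the per-cell mitochondrial
    load (which makes a realistic fraction of nanobiopsies fail the <30%
    mito filter).
    """

    n_genes: int = 2000
    n_noncoding: int = 100
    n_mito_genes: int = 20
    n_ribo_genes: int = 80
    module_size: int = 50
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.2
    module_log_mean: float = 1.0
    module_log_sd: float = 0.5
    dispersion: float = 0.5
    profile: str = "nanobiopsy"
    ribo_pct: float = 5.0
    effect_size: float = 2.0
    switch_p_untreated: float = 0.7
    switch_p_treated: float = 0.11
    cell_efficiency_sd: float = 0.1
    mito_noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        reserved = (
            self.n_noncoding + self.n_mito_genes + self.n_ribo_genes + 2 * self.module_size
        )
        if reserved >= self.n_genes:
            raise InvalidParameterError("gene groups exceed n_genes")
        if self.profile not in CAPTURE_PROFILES:
            raise InvalidParameterError(f"unknown capture profile '{self.profile}'")
        for p in (self.switch_p_untreated, self.switch_p_treated):
            if not (0 <= p <= 1):
                raise InvalidParameterError("switch probabilities must be in [0, 1]")
        if self.dispersion <= 0 or self.module_size <= 0:
            raise InvalidParameterError("dispersion and module_size must be positive")
        targets = CAPTURE_PROFILES[self.profile]
        n_pc = self.n_genes - self.n_noncoding
        if targets["target_expressed_genes"] >= n_pc:
            raise InvalidParameterError(
                f"target of {targets['target_expressed_genes']} expressed genes not "
                f"attainable with {n_pc} protein-coding genes"
            )


def _gene_table(config: GeneratorConfig) -> pd.DataFrame:
    """Deterministic gene universe: ids, flags and module membership."""
    n = config.n_genes
    width = len(str(n))
    ids, pc, mito, ribo, module = [], [], [], [], []

    def add(prefix, count, is_pc, is_mito, is_ribo, mod):
        start = len(ids)
        for i in range(count):
            ids.append(f"{prefix}{start + i:0{width}d}")
            pc.append(is_pc)
            mito.append(is_mito)
            ribo.append(is_ribo)
            module.append(mod)

    add("NCG", config.n_noncoding, False, False, False, "")
    add("MTG", config.n_mito_genes, True, True, False, "")
    add("RPG", config.n_ribo_genes, True, False, True, "")
    add("PNG", config.module_size, True, False, False, "PN")
    add("MSG", config.module_size, True, False, False, "MES")
    add("CDG", n - len(ids), True, False, False, "")
    return pd.DataFrame(
        {"protein_coding": pc, "mito": mito, "ribo": ribo, "module": module},
        index=pd.Index(ids, name="gene_id"),
    )


def gene_sets(config: GeneratorConfig) -> dict:
    """The PN and MES gene sets matching the generator's planted modules."""
    genes = _gene_table(config)
    return {
        "PN": genes.index[genes["module"] == "PN"].tolist(),
        "MES": genes.index[genes["module"] == "MES"].tolist(),
    }


def _base_shares(config: GeneratorConfig, genes: pd.DataFrame) -> np.ndarray:
    """Gene-level relative expression, normalised so that the
    mitochondrial and ribosomal shares hit the profile targets."""
    rng = np.random.default_rng(config.seed)  # gene-level params only
    raw = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, len(genes))
    is_module = (genes["module"] != "").to_numpy()
    raw[is_module] = rng.lognormal(
        config.module_log_mean, config.module_log_sd, int(is_module.sum())
    )
    mito = genes["mito"].to_numpy(bool)
    ribo = genes["ribo"].to_numpy(bool)
    other = ~(mito | ribo)
    target_mito = CAPTURE_PROFILES[config.profile]["target_mito_pct"] / 100.0
    target_ribo = config.ribo_pct / 100.0
    shares = raw.copy()
    shares[mito] *= target_mito / raw[mito].sum()
    shares[ribo] *= target_ribo / raw[ribo].sum()
    shares[other] *= (1.0 - target_mito - target_ribo) / raw[other].sum()
    return shares


def _nb_p_zero(mean: np.ndarray, alpha: float) -> np.ndarray:
    theta = 1.0 / alpha
    return (theta / (theta + mean)) ** theta


def _calibrate_depth(shares: np.ndarray, pc_mask: np.ndarray, alpha: float, target: float) -> float:
    """Per-cell depth such that the expected number of expressed
    protein-coding genes equals the profile target."""

    def expected_expressed(depth: float) -> float:
        return float((1.0 - _nb_p_zero(depth * shares[pc_mask], alpha)).sum())

    lo, hi = 1.0, 1.0
    while expected_expressed(hi) < target:
        hi *= 4.0
        if hi > 1e12:
            raise InvalidParameterError("expressed-gene target not attainable")
    while expected_expressed(lo) > target:
        lo /= 4.0
    return float(brentq(lambda d: expected_expressed(d) - target, lo, hi, rtol=1e-6))


def gen_counts(
    config: GeneratorConfig,
    n_cells: int,
    phenotypes,
    seed: int | None = None,
    cell_meta: pd.DataFrame | None = None,
) -> CountsMatrix:
    """Negative-binomial counts for ``n_cells`` cells of given phenotypes.

    ``phenotypes`` is a sequence of 'PN'/'MES' (or '' for no module
    shift).  The gene universe and baseline profile depend only on the
    config, so repeated calls share gene sets; the counts depend on
    ``seed`` (defaults to ``config.seed``) and are bit-reproducible.
    """
    phenotypes = list(phenotypes)
    if len(phenotypes) != n_cells:
        raise InvalidParameterError("one phenotype per cell is required")
    genes = _gene_table(config)
    shares = _base_shares(config, genes)
    pc_mask = genes["protein_coding"].to_numpy(bool)
    target = CAPTURE_PROFILES[config.profile]["target_expressed_genes"]

    rng = np.random.default_rng(config.seed if seed is None else seed)
    theta = 1.0 / config.dispersion
    mito = genes["mito"].to_numpy(bool)
    ribo = genes["ribo"].to_numpy(bool)
    pn = (genes["module"] == "PN").to_numpy()
    mes = (genes["module"] == "MES").to_numpy()
    block = ~(mito | ribo)  # phenotype boost renormalised within this block
    block_share = shares[block].sum()

    # phenotype-specific share profiles, each with its own calibrated
    # depth, so technical covariates (expressed-gene count, mito fraction)
    # are independent of the planted biology
    profiles: dict = {}
    for phen in set(phenotypes):
        cell_shares = shares.copy()
        if phen == "PN":
            cell_shares[pn] *= math.exp(config.effect_size)
        elif phen == "MES":
            cell_shares[mes] *= math.exp(config.effect_size)
        elif phen not in ("", None):
            raise InvalidParameterError(f"unknown phenotype '{phen}'")
        # keep the mitochondrial/ribosomal fractions at their targets: the
        # module boost redistributes mass only within the other genes
        cell_shares[block] *= block_share / cell_shares[block].sum()
        cell_shares /= cell_shares.sum()
        depth = _calibrate_depth(cell_shares, pc_mask, config.dispersion, target)
        profiles[phen] = (cell_shares, depth)

    cols = np.zeros((len(genes), n_cells), dtype=np.int64)
    for c, phen in enumerate(phenotypes):
        base_shares_c, depth = profiles[phen]
        cell_shares = base_shares_c.copy()
        if config.mito_noise_sd > 0:
            cell_shares[mito] *= rng.lognormal(
                -config.mito_noise_sd**2 / 2.0, config.mito_noise_sd
            )
        cell_shares /= cell_shares.sum()
        eff = 1.0
        if config.cell_efficiency_sd > 0:
            eff = rng.lognormal(-config.cell_efficiency_sd**2 / 2.0, config.cell_efficiency_sd)
        mean = depth * eff * cell_shares
        cols[:, c] = rng.negative_binomial(theta, theta / (theta + mean))

    if cell_meta is None:
        width = len(str(max(n_cells, 1)))
        cell_meta = pd.DataFrame(
            {"phenotype": phenotypes},
            index=pd.Index([f"cell{i:0{width}d}" for i in range(n_cells)], name="cell_id"),
        )
    return CountsMatrix(sp.csr_matrix(cols), genes, cell_meta)


def gen_paired_cohort(
    config: GeneratorConfig,
    n_pairs_untreated: int = 10,
    n_pairs_treated: int = 9,
    n_day1_only: int = 100,
    seed: int | None = None,
) -> tuple:
    """Paired day-1 / day-4 nanobiopsy cohort with planted switches.

    Day-1 phenotypes are uniform over {PN, MES}; the day-4 phenotype flips
    with the arm's switch probability.  ``n_day1_only`` unpaired day-1
    biopsies accompany the pairs, mirroring the study design in which the
    longitudinal samples are normalised and scaled jointly with the much
    larger day-1 cohort.  Returns ``(CountsMatrix, truth)`` where
    ``truth`` records the planted phenotypes and switch flags per pair
    for oracle testing.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records = []
    for arm, n_pairs, p_switch in (
        ("untreated", n_pairs_untreated, config.switch_p_untreated),
        ("treated", n_pairs_treated, config.switch_p_treated),
    ):
        for k in range(n_pairs):
            day1 = "PN" if rng.uniform() < 0.5 else "MES"
            switched = bool(rng.uniform() < p_switch)
            day4 = ({"PN": "MES", "MES": "PN"}[day1]) if switched else day1
            records.append(
                {
                    "pair_id": f"{arm[0].upper()}{k:03d}",
                    "treated": arm == "treated",
                    "day1_phenotype": day1,
                    "day4_phenotype": day4,
                    "switched": switched,
                }
            )
    truth = pd.DataFrame(records).set_index("pair_id")

    phenotypes, meta = [], []
    for k in range(n_day1_only):
        phen = "PN" if rng.uniform() < 0.5 else "MES"
        phenotypes.append(phen)
        meta.append(
            {
                "cell_id": f"D{k:03d}_day1",
                "group": "NB_Day1",
                "pair_id": None,
                "timepoint": "day1",
                "treated": False,
            }
        )
    for pair_id, row in truth.iterrows():
        for timepoint, phen in (("day1", row["day1_phenotype"]), ("day4", row["day4_phenotype"])):
            phenotypes.append(phen)
            meta.append(
                {
                    "cell_id": f"{pair_id}_{timepoint}",
                    "group": "NB_T" if row["treated"] else "NB_U",
                    "pair_id": pair_id,
                    "timepoint": timepoint,
                    "treated": bool(row["treated"]),
                }
            )
    cell_meta = pd.DataFrame(meta).set_index("cell_id")
    counts_seed = int(rng.integers(2**31 - 1))
    matrix = gen_counts(config, len(phenotypes), phenotypes, seed=counts_seed, cell_meta=cell_meta)
    return matrix, truth


# --- hand-constructed deterministic toy fixture ---------------------------

FIXTURE_THRESHOLDS = {"min_genes": 10, "max_ribo_pct": 10.0, "max_mito_pct": 30.0}
FIXTURE_PASS_CELLS = list(range(8))  # cells c00..c07 pass by construction
# coding genes with >3 counts in >=2 cells: the 12 block genes + g21
FIXTURE_KEPT_GENES = [f"g{i:02d}" for i in range(8, 20)] + ["g21"]


def fixture_toy_counts() -> CountsMatrix:
    """Deterministic 30-gene x 12-cell toy matrix with a known QC design.

    Cells 0-7 express 12 protein-coding genes with low mitochondrial and
    ribosomal load and pass the (scaled-down) thresholds; cell 8 expresses
    too few genes, cell 9 has 40% mitochondrial counts, cell 10 has 25%
    ribosomal counts and cell 11 is empty.  Gene g20 exceeds 3 counts in
    only one cell (dropped), g21 in two (kept), g22 never (dropped), and
    the non-coding g00 is expressed everywhere but excluded by flag.
    """
    counts = np.zeros((30, 12), dtype=np.int64)
    block = slice(8, 20)  # the 12 well-expressed coding genes
    for c in range(8):
        counts[block, c] = 5
        counts[0, c] = 5  # non-coding, expressed but never counted as PC
        counts[2, c] = 2  # mito trickle
        counts[5, c] = 1  # ribo trickle
        counts[22, c] = 3  # never exceeds the >3 gene-filter bar
    counts[8:13, 8] = 5  # cell 8: only 5 PC genes
    counts[block, 9] = 5
    counts[2, 9] = 40  # cell 9: 40% mito
    counts[block, 10] = 5
    counts[5, 10] = 20  # cell 10: 25% ribo
    counts[20, 0] = 4  # g20: >3 in one cell only
    counts[21, 0] = 4
    counts[21, 1] = 4  # g21: >3 in two cells

    gene_ids = [f"g{i:02d}" for i in range(30)]
    genes = pd.DataFrame(
        {
            "protein_coding": [i >= 2 for i in range(30)],
            "mito": [2 <= i <= 4 for i in range(30)],
            "ribo": [5 <= i <= 7 for i in range(30)],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    cells = pd.DataFrame(
        index=pd.Index([f"c{i:02d}" for i in range(12)], name="cell_id")
    )
    return CountsMatrix(sp.csr_matrix(counts), genes, cells)
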