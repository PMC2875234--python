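"""Calibration and recovery experiments on synthetic data.

These routines quantify how well the inference machinery recovers known
truth: omega recovery under the one-ratio model, the null distribution of
the branch-model LRT, its power against an elevated foreground omega, and
end-to-end group-level detection of a planted maternal divergence signal.
They are used both by the test suite and by the acceptance script.

Simulation conditions are model-matched (uniform root frequencies, no
gene-rate dispersion) so that deviations measure inference error, not
model misspecification; the dataset-level experiments use the generator's
realistic defaults instead.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .align import MultiCodonAlignment
from .branch import fit_branch_models
from .groups import compare_groups, summarize
from .simulate import (
    QUARTET,
    SimulationSpec,
    null_spec,
    planted_divergence_spec,
    simulate_gene_tables,
    simulate_quartet,
)


def _quartet_alignment(spec: SimulationSpec, rng, omega, foreground_omega=None):
    """Simulate one quartet and stack it as a (gap-free) codon alignment."""
    seqs, truth = simulate_quartet(
        spec, "sim", rng, omega=omega, foreground_omega=foreground_omega
    )
    rows = tuple(seqs[sp].dna for sp in QUARTET)
    return MultiCodonAlignment("sim", QUARTET, rows), truth


def _model_matched_spec(codons: int) -> SimulationSpec:
    return SimulationSpec(codons=codons, gene_rate_sd=0.0, cpg_bias=1.0)


@dataclass
class OmegaRecovery:
    estimates: list[float]
    truth: float

    @property
    def mean_estimate(self) -> float:
        return float(np.mean(self.estimates))

    @property
    def mean_error(self) -> float:
        return self.mean_estimate - self.truth


def omega_recovery(
    n_replicates: int = 20, codons: int = 500, omega: float = 0.2, seed: int = 0
) -> OmegaRecovery:
    """Fit the one-ratio model to quartets simulated at a known omega."""
    from .branch import CodonBranchModel

    spec = _model_matched_spec(codons)
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_replicates):
        aln, _ = _quartet_alignment(spec, rng, omega)
        one = CodonBranchModel(aln).fit("one_ratio", n_starts=1, seed=seed)
        estimates.append(one.params.omega_background)
    return OmegaRecovery(estimates, omega)


@dataclass
class LrtCalibration:
    statistics: list[float]
    directions: list[str]
    threshold: float = 2.71

    @property
    def two_sided_rate(self) -> float:
        """Fraction of replicates with 2*dlnL >= threshold (any direction)."""
        return float(np.mean([s >= self.threshold for s in self.statistics]))

    @property
    def directional_rate(self) -> float:
        """Fraction rejecting with the foreground omega on the elevated
        side: the one-sided rate that the 1/2 delta_0 + 1/2 chi2_1
        convention prices at 0.05 for threshold 2.71."""
        return float(
            np.mean([
                s >= self.threshold and d == "elevated"
                for s, d in zip(self.statistics, self.directions)
            ])
        )


def null_lrt_calibration(
    n_replicates: int = 200, codons: int = 250, omega: float = 0.13, seed: int = 0
) -> LrtCalibration:
    """Null distribution of the LRT: data generated with one shared omega."""
    spec = _model_matched_spec(codons)
    rng = np.random.default_rng(seed)
    stats, dirs = [], []
    for _ in range(n_replicates):
        aln, _ = _quartet_alignment(spec, rng, omega)
        _, _, res = fit_branch_models(aln, n_starts=1, seed=seed)
        stats.append(res.statistic)
        dirs.append(res.direction)
    return LrtCalibration(stats, dirs)


def lrt_power(
    n_replicates: int = 20,
    codons: int = 500,
    omega_background: float = 0.1,
    omega_foreground: float = 0.8,
    seed: int = 0,
) -> LrtCalibration:
    """LRT behaviour when the foreground branch truly has a distinct omega."""
    spec = _model_matched_spec(codons)
    rng = np.random.default_rng(seed)
    stats, dirs = [], []
    for _ in range(n_replicates):
        aln, _ = _quartet_alignment(
            spec, rng, omega_background, foreground_omega=omega_foreground
        )
        _, _, res = fit_branch_models(aln, n_starts=1, seed=seed)
        stats.append(res.statistic)
        dirs.append(res.direction)
    return LrtCalibration(stats, dirs)


# ---------------------------------------------------------------------------
# End-to-end group-level experiments


@dataclass
class GroupExperiment:
    """Maternal-vs-background outcome of one simulated dataset."""

    mean_by_group: dict[str, dict[str, float]]
    p_cdna_identity: float
    p_ka_ks: float
    identity_ordered: bool  # maternal cDNA identity below background
    kaks_ordered: bool  # maternal Ka/Ks above background


def _pair_values(dataset, stat_pairs=(("human", "mouse"),)):
    values: dict[str, dict[str, float]] = {}
    wanted = {frozenset(p) for p in stat_pairs}
    for r in dataset.pair_records:
        if frozenset((r.species_a, r.species_b)) not in wanted:
            continue
        values[r.gene_id] = {
            "protein_identity": r.protein_identity,
            "cdna_identity": r.cdna_identity,
            "ka_ks": r.ka_ks,
            "ks": None if r.ks_discarded else r.ks,
        }
    return values


def group_experiment(spec: SimulationSpec, seed: int) -> GroupExperiment:
    """Simulate a dataset, summarize human-mouse divergence by group and
    compare the maternal group against the background by rank sum."""
    dataset = simulate_gene_tables(spec, seed=seed)
    values = _pair_values(dataset)
    group_of = {a.gene_id: a.group for a in dataset.assignments}

    pools: dict[str, dict[str, list[float]]] = {}
    for gene, d in values.items():
        grp = group_of[gene]
        for stat, v in d.items():
            if v is not None:
                pools.setdefault(grp, {}).setdefault(stat, []).append(v)

    summaries = summarize(values, dataset.assignments)
    mean_by_group = {}
    for s in summaries:
        if s.mean is not None:
            mean_by_group.setdefault(s.group, {})[s.statistic] = s.mean

    cmp_id = compare_groups(
        pools["maternal"]["cdna_identity"], pools["background"]["cdna_identity"]
    )
    cmp_w = compare_groups(pools["maternal"]["ka_ks"], pools["background"]["ka_ks"])
    mat, bgd = mean_by_group["maternal"], mean_by_group["background"]
    return GroupExperiment(
        mean_by_group=mean_by_group,
        p_cdna_identity=cmp_id.p_value,
        p_ka_ks=cmp_w.p_value,
        identity_ordered=mat["cdna_identity"] < bgd["cdna_identity"],
        kaks_ordered=mat["ka_ks"] > bgd["ka_ks"],
    )


def planted_group_experiment(seed: int = 0, codons: int = 200) -> GroupExperiment:
    """Planted maternal divergence (elevated omega, faster clock) at reduced
    desk-scale sample sizes."""
    spec = planted_divergence_spec(codons=codons, seed=seed)
    for name in spec.groups:
        g = spec.groups[name]
        spec.groups[name] = dataclasses.replace(
            g, n_genes={"maternal": 24, "paternal": 0, "background": 60}[name]
        )
    return group_experiment(spec, seed)


def null_group_rejection_rate(
    n_runs: int = 20, seed: int = 0, codons: int = 150
) -> tuple[float, list[float]]:
    """Fraction of all-groups-equal datasets where the maternal-vs-background
    cDNA-identity comparison is (spuriously) significant at 0.05."""
    p_values = []
    for i in range(n_runs):
        spec = null_spec(n_per_group=(20, 0, 40), codons=codons, seed=seed + i)
        exp = group_experiment(spec, seed=seed + i)
        p_values.append(exp.p_cdna_identity)
    rate = float(np.mean([p < 0.05 for p in p_values]))
    return rate, p_values
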