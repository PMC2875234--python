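"""Synthetic data with controlled ground truth.

Codon quartets are evolved under exactly the rate-matrix code the branch
models use for inference, so generator and likelihood agree on the process
by construction.  Ortholog pair tables are produced by running the *real*
alignment and divergence stages on the simulated sequences — never by
drawing summary numbers directly — while paralog and SNP tables are drawn
from per-group distributions.

Default parameters emulate the comparative setting the pipeline targets:
maternal (n=26) and paternal (n=27) imprinted gene groups against a
desk-scale subsample of the genomic background; quartet branch lengths that
put human-rodent synonymous divergence near Ks ~ 0.6 and mouse-rat near
~ 0.2; purifying selection with background omega 0.13 and a slightly
elevated maternal omega; paralog frequencies and identities shaped like
Ensembl counts (about 61% of imprinted and 48% of background genes with a
paralog); SNP densities with medians near 2.4/kb (imprinted) and 3.6/kb
(background).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import align_codon_pair
from .branch import BRANCHES, QuartetTree
from .codonmodel import CODONS, get_rate_model, uniform_frequencies
from .divergence import count_gaps, nei_gojobori, percent_identity
from .io import (
    CodingSequence,
    GeneGroupAssignment,
    GenePairRecord,
    ParalogRecord,
    SnpRecord,
    write_fasta,
    write_gene_pair_table,
    write_group_file,
    write_paralog_table,
    write_snp_table,
)

QUARTET = ("human", "mouse", "rat", "cow")


@dataclass
class GroupParams:
    """Evolutionary and table-shape parameters for one gene group."""

    n_genes: int
    omega: float
    foreground_omega: float | None = None  # None: same as omega
    rate_multiplier: float = 1.0  # scales every branch length
    paralog_prob: float = 0.5
    paralog_identity_mean: float = 55.0
    paralog_identity_sd: float = 20.0
    x_paralog_prob: float = 0.04
    snp_median_per_kb: float = 3.6
    snp_sigma: float = 0.45


@dataclass
class SimulationSpec:
    """Full description of one synthetic dataset."""

    codons: int = 300
    kappa: float = 2.0
    branch_lengths: dict[str, float] = field(
        default_factory=lambda: {
            "human": 0.35, "mouse": 0.12, "rat": 0.14, "cow": 0.40, "ancestor": 0.25,
        }
    )
    gene_rate_sd: float = 0.3  # lognormal sd of the per-gene rate multiplier
    cpg_bias: float = 1.5  # root weight multiplier for codons ending in C
    codon_deletion_prob: float = 0.0  # per-gene chance of one whole-codon deletion
    seed: int = 0
    groups: dict[str, GroupParams] = field(
        default_factory=lambda: {
            "maternal": GroupParams(
                n_genes=26, omega=0.16, paralog_prob=0.607,
                paralog_identity_mean=47.1, paralog_identity_sd=15.2,
                x_paralog_prob=0.088, snp_median_per_kb=2.4,
            ),
            "paternal": GroupParams(
                n_genes=27, omega=0.136, paralog_prob=0.607,
                paralog_identity_mean=47.1, paralog_identity_sd=15.2,
                x_paralog_prob=0.088, snp_median_per_kb=2.4,
            ),
            "background": GroupParams(
                n_genes=120, omega=0.13, paralog_prob=0.482,
                paralog_identity_mean=56.9, paralog_identity_sd=22.7,
                x_paralog_prob=0.030, snp_median_per_kb=3.6,
            ),
        }
    )

    def validate(self) -> None:
        if self.codons < 2 or self.kappa <= 0 or self.cpg_bias <= 0:
            raise ValueError("codons must be >= 2 and kappa, cpg_bias positive")
        if set(self.branch_lengths) != set(BRANCHES):
            raise ValueError(f"branch lengths must name exactly {BRANCHES}")
        for name, g in self.groups.items():
            if g.omega <= 0 or g.n_genes < 0 or not 0 <= g.paralog_prob <= 1:
                raise ValueError(f"group {name}: invalid parameters")

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "SimulationSpec":
        d = json.loads(Path(path).read_text())
        if "groups" in d:
            d["groups"] = {k: GroupParams(**v) for k, v in d["groups"].items()}
        spec = cls(**d)
        spec.validate()
        return spec


def _root_frequencies(cpg_bias: float) -> np.ndarray:
    w = np.array([cpg_bias if c.endswith("C") else 1.0 for c in CODONS])
    return w / w.sum()


def _evolve(states: np.ndarray, kappa: float, omega: float, t: float,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve codon states for time t by sampling from P(t) rows."""
    if t == 0:
        return states.copy()
    p = get_rate_model(kappa, omega, uniform_frequencies()).transition_matrix(t)
    out = np.empty_like(states)
    for s in np.unique(states):
        mask = states == s
        out[mask] = rng.choice(len(CODONS), size=int(mask.sum()), p=p[s])
    return out


@dataclass
class QuartetTruth:
    """Generating parameters of one simulated quartet."""

    tree: QuartetTree
    kappa: float
    omega_background: float
    omega_foreground: float


def simulate_quartet(
    spec: SimulationSpec,
    gene_id: str,
    rng: np.random.Generator,
    omega: float | None = None,
    foreground_omega: float | None = None,
    rate_multiplier: float = 1.0,
) -> tuple[dict[str, CodingSequence], QuartetTruth]:
    """Evolve one codon quartet along the fixed tree.

    The root sequence is drawn from the (optionally CpG-biased) sense-codon
    distribution; each branch applies the same substitution process the
    likelihood uses.  The chain is rooted at the human/cow junction, which
    by reversibility is equivalent to any other rooting.
    """
    spec.validate()
    w_bg = spec.groups["background"].omega if omega is None else omega
    w_fg = w_bg if foreground_omega is None else foreground_omega
    bl = {b: t * rate_multiplier for b, t in spec.branch_lengths.items()}
    root = rng.choice(len(CODONS), size=spec.codons, p=_root_frequencies(spec.cpg_bias))

    k = spec.kappa
    human = _evolve(root, k, w_bg, bl["human"], rng)
    cow = _evolve(root, k, w_bg, bl["cow"], rng)
    rodent_anc = _evolve(root, k, w_fg, bl["ancestor"], rng)
    mouse = _evolve(rodent_anc, k, w_bg, bl["mouse"], rng)
    rat = _evolve(rodent_anc, k, w_bg, bl["rat"], rng)

    tips = {"human": human, "mouse": mouse, "rat": rat, "cow": cow}
    seqs = {}
    for sp, states in tips.items():
        dna = "".join(CODONS[s] for s in states)
        if spec.codon_deletion_prob > 0 and sp != "human":
            if rng.random() < spec.codon_deletion_prob:
                n_del = int(rng.integers(1, 4))
                start = int(rng.integers(0, spec.codons - n_del)) * 3
                dna = dna[:start] + dna[start + 3 * n_del :]
        seqs[sp] = CodingSequence(gene_id, sp, dna, frame_validated=True)
    truth = QuartetTruth(QuartetTree(bl), k, w_bg, w_fg)
    return seqs, truth


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the generating truth."""

    quartets: dict[str, dict[str, CodingSequence]]
    truths: dict[str, QuartetTruth]
    pair_records: list[GenePairRecord]
    paralog_records: list[ParalogRecord]
    snp_records: list[SnpRecord]
    assignments: list[GeneGroupAssignment]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        all_seqs = [s for q in self.quartets.values() for s in q.values()]
        write_fasta(all_seqs, out / "sequences.fasta")
        write_gene_pair_table(self.pair_records, out / "pairs.tsv")
        write_paralog_table(self.paralog_records, out / "paralogs.tsv")
        write_snp_table(self.snp_records, out / "snps.tsv")
        write_group_file(self.assignments, out / "groups.tsv")


_PAIRS = (("human", "mouse"), ("human", "rat"), ("mouse", "rat"))


def simulate_gene_tables(spec: SimulationSpec, seed: int | None = None) -> SyntheticDataset:
    """Generate the full table bundle for every gene in every group.

    Ortholog pair rows are computed by actually aligning the simulated
    sequences and running Nei-Gojobori on the codon alignments.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    quartets: dict[str, dict[str, CodingSequence]] = {}
    truths: dict[str, QuartetTruth] = {}
    pair_records: list[GenePairRecord] = []
    paralog_records: list[ParalogRecord] = []
    snp_records: list[SnpRecord] = []
    assignments: list[GeneGroupAssignment] = []

    for group_name in sorted(spec.groups):
        g = spec.groups[group_name]
        for i in range(g.n_genes):
            gene_id = f"{group_name[:3]}{i:04d}"
            rate = float(np.exp(rng.normal(0.0, spec.gene_rate_sd)))
            seqs, truth = simulate_quartet(
                spec, gene_id, rng,
                omega=g.omega, foreground_omega=g.foreground_omega,
                rate_multiplier=rate * g.rate_multiplier,
            )
            quartets[gene_id] = seqs
            truths[gene_id] = truth

            for sp_a, sp_b in _PAIRS:
                pa, ca = align_codon_pair(seqs[sp_a], seqs[sp_b])
                kaks = nei_gojobori(ca)
                pair_records.append(
                    GenePairRecord(
                        gene_id=gene_id, species_a=sp_a, species_b=sp_b,
                        protein_identity=round(percent_identity(pa), 4),
                        cdna_identity=round(percent_identity(ca), 4),
                        gap_count=count_gaps(pa),
                        ka=None if kaks.Ka is None else round(kaks.Ka, 6),
                        ks=None if kaks.Ks is None else round(kaks.Ks, 6),
                    )
                )

            has_paralog = bool(rng.random() < g.paralog_prob)
            if has_paralog:
                n_par = 1 + int(rng.poisson(1.0))
                on_x = rng.random() < g.x_paralog_prob
                ident = float(np.clip(
                    rng.normal(g.paralog_identity_mean, g.paralog_identity_sd), 1.0, 99.9,
                ))
                paralog_records.append(
                    ParalogRecord(
                        gene_id=gene_id, paralog_id=f"{gene_id}_p1", rank=1,
                        paralog_chromosome="X" if on_x else str(int(rng.integers(1, 23))),
                        protein_identity=round(ident, 2), n_paralogs=n_par,
                    )
                )
            coding_length = 3 * spec.codons
            density = float(
                np.exp(rng.normal(np.log(g.snp_median_per_kb), g.snp_sigma))
            )
            snp_records.append(
                SnpRecord(gene_id, coding_length, int(rng.poisson(density * coding_length / 1000.0)))
            )
            assignments.append(GeneGroupAssignment(gene_id, group_name, has_paralog))

    return SyntheticDataset(
        quartets, truths, pair_records, paralog_records, snp_records, assignments
    )


def null_spec(n_per_group: tuple[int, int, int] = (24, 24, 72), codons: int = 200,
              seed: int = 0) -> SimulationSpec:
    """A dataset with identical evolutionary parameters across groups (the
    table-shape parameters also equalized), for calibration runs."""
    spec = SimulationSpec(codons=codons, seed=seed)
    base = GroupParams(n_genes=0, omega=0.13, paralog_prob=0.5,
                       snp_median_per_kb=3.0)
    for name, n in zip(("maternal", "paternal", "background"), n_per_group):
        g = dataclasses.replace(base, n_genes=n)
        spec.groups[name] = g
    return spec


def planted_divergence_spec(codons: int = 300, seed: int = 0) -> SimulationSpec:
    """Defaults plus a deliberately strong maternal-group signal: elevated
    omega and a faster clock, giving lower identities and a higher Ka/Ks in
    the maternal group that is detectable at desk-scale sample sizes."""
    spec = SimulationSpec(codons=codons, seed=seed)
    spec.groups["maternal"] = dataclasses.replace(
        spec.groups["maternal"], omega=0.35, rate_multiplier=1.6,
    )
    return spec


TOY_SEED = 20090217


def fixture_toy_dataset(out_dir=None) -> SyntheticDataset:
    """Deterministic 6-gene, 30-codon bundle used by docs and smoke tests.

    Rodent branches are shortened so that mouse-rat similarity exceeds both
    human-rodent similarities for every gene, making triangulation
    applicable throughout by construction.
    """
    spec = SimulationSpec(
        codons=30,
        seed=TOY_SEED,
        branch_lengths={
            "human": 0.30, "mouse": 0.03, "rat": 0.03, "cow": 0.35, "ancestor": 0.20,
        },
        gene_rate_sd=0.0,
    )
    for name in spec.groups:
        spec.groups[name] = dataclasses.replace(spec.groups[name], n_genes=2)
    ds = simulate_gene_tables(spec)
    if out_dir is not None:
        ds.write(out_dir)
    return ds
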