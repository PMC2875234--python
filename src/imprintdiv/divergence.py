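"""Per-gene-pair divergence statistics.

Percent identity and indel counts from the alignments, synonymous and
nonsynonymous rates by the Nei-Gojobori counting method with Jukes-Cantor
multiple-hit correction, the silent-CpG mutability index (a methyl-cytosine
deamination signature at third codon positions) and SNP density per kb of
coding sequence.

Nei-Gojobori conventions used here:

* the synonymous site fraction of a codon position is the number of the
  three possible single-nucleotide changes that are synonymous, divided by
  three; changes to stop codons contribute to neither numerator (they are
  counted as nonsynonymous sites via N = 3 - S), so S + N = 3 per codon;
* sites are averaged over the two sequences;
* codon pairs differing at several positions are scored by averaging the
  synonymous/nonsynonymous step counts over all minimal mutational
  pathways, excluding pathways that pass through a stop codon;
* p-distances are corrected with d = -(3/4) ln(1 - (4/3) p); p >= 3/4 is
  flagged as saturation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from .align import CodonAlignment, ProteinAlignment
from .codonmodel import AMINO_ACIDS, CODON_INDEX, STOP_CODONS
from .io import SnpRecord

_NUCS = "ACGT"


class EmptyAlignmentError(ValueError):
    """No comparable codon columns after removing gaps and ambiguity."""


# ---------------------------------------------------------------------------
# Identity and gap statistics


def percent_identity(
    alignment: ProteinAlignment | CodonAlignment,
    denominator: str = "all_columns",
) -> float:
    """100 x identical non-gap columns / denominator.

    ``all_columns`` counts gap columns in the denominator (so gaps act as
    mismatches); ``ungapped_columns`` restricts to columns where both rows
    have a residue.  Symmetric in the two rows.
    """
    a, b = alignment.rows
    if not a:
        raise EmptyAlignmentError("empty alignment")
    identical = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    if denominator == "all_columns":
        denom = len(a)
    elif denominator == "ungapped_columns":
        denom = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
        if denom == 0:
            raise EmptyAlignmentError("no ungapped columns")
    else:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    return 100.0 * identical / denom


def count_gaps(alignment: ProteinAlignment | CodonAlignment, mode: str = "events") -> int:
    """Number of indel events (maximal gap runs over both rows) or gap columns."""
    a, b = alignment.rows
    if mode == "columns":
        return sum(1 for x, y in zip(a, b) if x == "-" or y == "-")
    if mode != "events":
        raise ValueError(f"unknown gap-count mode {mode!r}")
    events = 0
    for row in (a, b):
        in_gap = False
        for ch in row:
            if ch == "-" and not in_gap:
                events += 1
                in_gap = True
            elif ch != "-":
                in_gap = False
    return events


# ---------------------------------------------------------------------------
# Nei-Gojobori


@dataclass
class KaKsResult:
    """Counting-method Ka/Ks with site/difference decomposition."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    saturated: bool
    n_codons: int

    @property
    def ka_ks(self) -> float | None:
        if self.Ka is None or self.Ks is None or self.Ks <= 0:
            return None
        return self.Ka / self.Ks


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Synonymous sites of one sense codon (sum of per-position fractions)."""
    aa = AMINO_ACIDS[CODON_INDEX[codon]]
    s = 0.0
    for pos in range(3):
        syn = 0
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if alt not in STOP_CODONS and AMINO_ACIDS[CODON_INDEX[alt]] == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all minimal mutational pathways that avoid stop codons."""
    diffs = [k for k in range(3) if c1[k] != c2[k]]
    if not diffs:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diffs):
        cur = c1
        sd = nd = 0
        blocked = False
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and step < len(order) - 1:
                blocked = True
                break
            if nxt in STOP_CODONS:  # endpoint is sense by precondition
                blocked = True
                break
            if AMINO_ACIDS[CODON_INDEX[cur]] == AMINO_ACIDS[CODON_INDEX[nxt]]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            totals.append((sd, nd))
    if not totals:
        # unreachable for sense-sense pairs under the standard code, but be safe:
        # fall back to counting every pathway, stops included
        for order in itertools.permutations(diffs):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                syn = (
                    nxt not in STOP_CODONS
                    and cur not in STOP_CODONS
                    and AMINO_ACIDS[CODON_INDEX[cur]] == AMINO_ACIDS[CODON_INDEX[nxt]]
                )
                sd += 1 if syn else 0
                nd += 0 if syn else 1
                cur = nxt
            totals.append((sd, nd))
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """d = -(3/4) ln(1 - (4/3) p); None at saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion of differences cannot be negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def comparable_codon_pairs(ca: CodonAlignment) -> list[tuple[str, str]]:
    """Codon columns with no gap, no N and no stop codon in either row."""
    a, b = ca.rows
    pairs = []
    for i in range(0, len(a), 3):
        ca_i, cb_i = a[i : i + 3], b[i : i + 3]
        if "-" in ca_i or "-" in cb_i or "N" in ca_i or "N" in cb_i:
            continue
        if ca_i in STOP_CODONS or cb_i in STOP_CODONS:
            continue
        pairs.append((ca_i, cb_i))
    return pairs


def nei_gojobori(ca: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori Ka/Ks over the comparable codon columns of an alignment."""
    pairs = comparable_codon_pairs(ca)
    if not pairs:
        raise EmptyAlignmentError(f"{ca.gene_id}: no comparable codon columns")
    S = sum((_syn_sites(x) + _syn_sites(y)) / 2.0 for x, y in pairs)
    N = 3.0 * len(pairs) - S
    Sd = Nd = 0.0
    for x, y in pairs:
        sd, nd = _pathway_differences(x, y)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS) if S > 0 else None
    Ka = jukes_cantor(pN) if N > 0 else None
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
        saturated=(Ks is None or Ka is None), n_codons=len(pairs),
    )


# ---------------------------------------------------------------------------
# Silent CpG mutability


@dataclass
class CpGMutabilityResult:
    """Third-position CpG context counts across a pairwise codon alignment.

    ``mutability_index`` is the TpG-mismatch fraction of all silent
    third-position CpG contexts; ``ratio_tpg_to_cpg`` is the raw
    CpG-TpG : CpG-CpG ratio.  Both views of the same counts are provided.
    """

    n_cpg_cpg: int
    n_cpg_tpg: int

    @property
    def mutability_index(self) -> float | None:
        denom = self.n_cpg_cpg + self.n_cpg_tpg
        return None if denom == 0 else self.n_cpg_tpg / denom

    @property
    def ratio_tpg_to_cpg(self) -> float | None:
        return None if self.n_cpg_cpg == 0 else self.n_cpg_tpg / self.n_cpg_cpg


def _is_silent_ct_change(codon: str) -> bool:
    """True if swapping C<->T at the third position keeps the amino acid
    (both variants must be sense codons)."""
    c_var = codon[:2] + "C"
    t_var = codon[:2] + "T"
    if c_var in STOP_CODONS or t_var in STOP_CODONS:
        return False
    return AMINO_ACIDS[CODON_INDEX[c_var]] == AMINO_ACIDS[CODON_INDEX[t_var]]


def silent_cpg_mutability(ca: CodonAlignment) -> CpGMutabilityResult:
    """Count third-position CpG-CpG and silent CpG-TpG dinucleotide pairs.

    The dinucleotide is the third base of codon i plus the first base of
    codon i+1.  A site is CpG-CpG when both rows read CG; it is CpG-TpG when
    one row reads CG, the other TG, and the C->T exchange at that third
    position is synonymous.  Sites where either codon i or codon i+1
    contains a gap or N in either row are skipped.
    """
    a, b = ca.rows
    n_cpg_cpg = n_cpg_tpg = 0
    for i in range(0, len(a) - 3, 3):
        cod_a1, cod_a2 = a[i : i + 3], a[i + 3 : i + 6]
        cod_b1, cod_b2 = b[i : i + 3], b[i + 3 : i + 6]
        window = cod_a1 + cod_a2 + cod_b1 + cod_b2
        if "-" in window or "N" in window:
            continue
        di_a = cod_a1[2] + cod_a2[0]
        di_b = cod_b1[2] + cod_b2[0]
        if di_a == "CG" and di_b == "CG":
            n_cpg_cpg += 1
        elif {di_a, di_b} == {"CG", "TG"}:
            # third-position C<->T must be silent in the shared codon context
            cpg_codon = cod_a1 if di_a == "CG" else cod_b1
            if cpg_codon not in STOP_CODONS and _is_silent_ct_change(cpg_codon):
                n_cpg_tpg += 1
    return CpGMutabilityResult(n_cpg_cpg, n_cpg_tpg)


# ---------------------------------------------------------------------------
# SNP density and the per-gene record


def snp_density(snp: SnpRecord) -> float:
    """SNPs per kb of coding sequence."""
    return snp.density_per_kb


@dataclass
class DivergenceRecord:
    """All pairwise statistics for one gene and one species pair."""

    gene_id: str
    species_a: str
    species_b: str
    protein_identity: float
    cdna_identity: float
    gap_count: int
    kaks: KaKsResult
    cpg: CpGMutabilityResult
    snp_density_per_kb: float | None = None


def divergence_record(
    pa: ProteinAlignment,
    ca: CodonAlignment,
    snp: SnpRecord | None = None,
    identity_denominator: str = "all_columns",
) -> DivergenceRecord:
    """Assemble the full statistics bundle for one aligned gene pair."""
    return DivergenceRecord(
        gene_id=ca.gene_id,
        species_a=ca.species_a,
        species_b=ca.species_b,
        protein_identity=percent_identity(pa, identity_denominator),
        cdna_identity=percent_identity(ca, identity_denominator),
        gap_count=count_gaps(pa),
        kaks=nei_gojobori(ca),
        cpg=silent_cpg_mutability(ca),
        snp_density_per_kb=None if snp is None else snp.density_per_kb,
    )
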