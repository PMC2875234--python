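"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written from first principles — recursive
enumeration, explicit state sums, event-driven simulation — and shares no
code with the package's computational paths.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy.linalg import expm

_CT = CodonTable.unambiguous_dna_by_id[1]
STOPS = set(_CT.stop_codons)
SENSE = sorted(c for c in _CT.forward_table if set(c) <= set("ACGT"))
NUCS = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# Nei-Gojobori


def ng_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) sites of one codon: per position, the
    fraction of the three single-base changes that are synonymous; stop
    targets count as nonsynonymous via n = 3 - s."""
    s = 0.0
    for pos in range(3):
        syn = sum(
            1
            for nuc in NUCS
            if nuc != codon[pos]
            and (alt := codon[:pos] + nuc + codon[pos + 1 :]) not in STOPS
            and _aa(alt) == _aa(codon)
        )
        s += syn / 3.0
    return s, 3.0 - s


def ng_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) averaged over all stop-free minimal pathways, by recursion."""

    def walk(cur: str) -> list[tuple[int, int]]:
        if cur == c2:
            return [(0, 0)]
        results = []
        for pos in range(3):
            if cur[pos] == c2[pos]:
                continue
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS and nxt != c2:
                continue
            step_syn = _aa(cur) == _aa(nxt)
            for sd, nd in walk(nxt):
                results.append((sd + (1 if step_syn else 0), nd + (0 if step_syn else 1)))
        return results

    paths = walk(c1)
    assert paths, f"no stop-free pathway between {c1} and {c2}"
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def ng_pair_counts(codons1: list[str], codons2: list[str]):
    """(S, N, Sd, Nd) for two gap-free codon sequences."""
    S = N = Sd = Nd = 0.0
    for a, b in zip(codons1, codons2):
        sa, na = ng_sites(a)
        sb, nb = ng_sites(b)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = ng_differences(a, b)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


# ---------------------------------------------------------------------------
# Global alignment enumeration


def enumerate_alignment_score(p1: str, p2: str, matrix, gap_open: float, gap_extend: float):
    """Maximum global alignment score by recursive enumeration of every
    alignment (exponential; for short sequences only).  A gap run of length
    L costs gap_open + (L - 1) * gap_extend, end gaps included."""

    best = [-np.inf]

    def rec(i: int, j: int, score: float, prev: str) -> None:
        if i == len(p1) and j == len(p2):
            best[0] = max(best[0], score)
            return
        if i < len(p1) and j < len(p2):
            rec(i + 1, j + 1, score + matrix[p1[i], p2[j]], "m")
        if i < len(p1):  # gap in p2
            cost = gap_extend if prev == "a" else gap_open
            rec(i + 1, j, score - cost, "a")
        if j < len(p2):  # gap in p1
            cost = gap_extend if prev == "b" else gap_open
            rec(i, j + 1, score - cost, "b")

    rec(0, 0, 0.0, "m")
    return best[0]


# ---------------------------------------------------------------------------
# Codon model: independent Q, exhaustive likelihood, Gillespie simulation


def _transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def oracle_rate_matrix(kappa: float, omega: float, freqs: np.ndarray) -> np.ndarray:
    n = len(SENSE)
    q = np.zeros((n, n))
    for i, ci in enumerate(SENSE):
        for j, cj in enumerate(SENSE):
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            rate = freqs[j]
            if _transition(ci[k], cj[k]):
                rate *= kappa
            if _aa(ci) != _aa(cj):
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -sum(freqs[i] * q[i, i] for i in range(n))
    return q / scale


def exhaustive_quartet_loglik(
    columns: list[tuple[int, int, int, int]],
    branch_lengths: dict[str, float],
    kappa: float,
    omega_background: float,
    omega_foreground: float,
    freqs: np.ndarray,
) -> float:
    """Log-likelihood by explicit summation over all 61 x 61 internal-node
    state pairs, with transition matrices from scipy.linalg.expm."""
    q_bg = oracle_rate_matrix(kappa, omega_background, freqs)
    q_fg = oracle_rate_matrix(kappa, omega_foreground, freqs)
    p = {
        "human": expm(q_bg * branch_lengths["human"]),
        "mouse": expm(q_bg * branch_lengths["mouse"]),
        "rat": expm(q_bg * branch_lengths["rat"]),
        "cow": expm(q_bg * branch_lengths["cow"]),
        "ancestor": expm(q_fg * branch_lengths["ancestor"]),
    }
    total = 0.0
    n = len(SENSE)
    for (h, m, r, c) in columns:
        site = 0.0
        for x in range(n):  # human/cow junction
            for y in range(n):  # rodent ancestor
                site += (
                    freqs[x]
                    * p["human"][x, h]
                    * p["cow"][x, c]
                    * p["ancestor"][x, y]
                    * p["mouse"][y, m]
                    * p["rat"][y, r]
                )
        total += np.log(site)
    return float(total)


def gillespie_evolve(
    states: np.ndarray,
    kappa: float,
    omega: float,
    t: float,
    freqs: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Event-driven simulation of the codon chain; returns (end states,
    total number of substitution events)."""
    q = oracle_rate_matrix(kappa, omega, freqs)
    out = states.copy()
    events = 0
    for i in range(len(out)):
        clock = 0.0
        s = int(out[i])
        while True:
            rate = -q[s, s]
            clock += rng.exponential(1.0 / rate)
            if clock >= t:
                break
            probs = q[s].copy()
            probs[s] = 0.0
            probs /= probs.sum()
            s = int(rng.choice(len(SENSE), p=probs))
            events += 1
        out[i] = s
    return out, events
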