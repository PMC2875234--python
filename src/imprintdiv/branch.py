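"""Branch-specific codon models on the fixed mammalian quartet.

The unrooted tree is (human, (mouse, rat) #1, cow): five branches, with the
internal branch leading to the mouse-rat ancestor marked as foreground.
Substitution follows the 61-state codon model of `codonmodel` with a single
kappa, branch lengths in expected substitutions per codon, and either one
shared omega (one-ratio model) or a separate omega on the foreground branch
(two-ratios model).  Model fit is judged by a likelihood-ratio test: twice
the log-likelihood difference is compared with 2.71, the 5% critical value
of the one-sided (boundary-mixture 1/2 delta_0 + 1/2 chi2_1) convention.

The modelling API follows the Model/Results pattern: build a
:class:`CodonBranchModel` from a quartet codon alignment, call
:meth:`~CodonBranchModel.fit`, and read estimates off the returned
:class:`BranchModelResults`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .align import MultiCodonAlignment
from .codonmodel import (
    CODON_INDEX,
    CODONS,
    STOP_CODONS,
    f1x4_frequencies,
    get_rate_model,
    synonymous_flow_fraction,
    uniform_frequencies,
)

QUARTET_SPECIES = ("human", "mouse", "rat", "cow")
BRANCHES = ("human", "mouse", "rat", "cow", "ancestor")
FOREGROUND_BRANCH = "ancestor"
LRT_THRESHOLD = 2.71
OMEGA_BOUNDS = (1e-4, 10.0)
KAPPA_BOUNDS = (0.05, 100.0)
LENGTH_BOUNDS = (1e-6, 20.0)


class DataError(ValueError):
    """Alignment content unusable for the codon model."""


@dataclass
class QuartetTree:
    """The fixed unrooted quartet with per-branch lengths.

    Branches are named by the tip they lead to, plus ``ancestor`` for the
    internal branch joining the mouse-rat node to the human/cow junction
    (the foreground branch).
    """

    branch_lengths: dict[str, float] = field(
        default_factory=lambda: {b: 0.1 for b in BRANCHES}
    )

    def __post_init__(self) -> None:
        if set(self.branch_lengths) != set(BRANCHES):
            raise ValueError(f"branch lengths must be given for exactly {BRANCHES}")
        for b, t in self.branch_lengths.items():
            if t < 0:
                raise ValueError(f"branch {b!r} has negative length {t}")

    def to_newick(self) -> str:
        bl = self.branch_lengths
        return (
            f"(human:{bl['human']:.6f},(mouse:{bl['mouse']:.6f},"
            f"rat:{bl['rat']:.6f})#1:{bl['ancestor']:.6f},cow:{bl['cow']:.6f});"
        )

    @classmethod
    def from_newick(cls, newick: str) -> "QuartetTree":
        """Parse '(human:x,(mouse:x,rat:x)#1:x,cow:x);' (tip order free
        within each level); validates the topology and the #1 mark."""
        s = newick.strip().rstrip(";").replace(" ", "")
        inner = re.search(r"\(([a-z]+):([\d.eE+-]+),([a-z]+):([\d.eE+-]+)\)#1:([\d.eE+-]+)", s)
        if not inner or {inner.group(1), inner.group(3)} != {"mouse", "rat"}:
            raise ValueError(
                "tree must contain the foreground-marked rodent clade "
                "'(mouse:?,rat:?)#1:?'"
            )
        lengths = {
            inner.group(1): float(inner.group(2)),
            inner.group(3): float(inner.group(4)),
            "ancestor": float(inner.group(5)),
        }
        rest = s.replace(inner.group(0), "")
        tips = dict(re.findall(r"([a-z]+):([\d.eE+-]+)", rest))
        if set(tips) != {"human", "cow"}:
            raise ValueError("tree must have exactly the tips human, mouse, rat, cow")
        lengths["human"] = float(tips["human"])
        lengths["cow"] = float(tips["cow"])
        return cls(lengths)


@dataclass
class CodonModelParams:
    kappa: float
    omega_background: float
    omega_foreground: float
    codon_frequencies: np.ndarray

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.omega_background <= 0 or self.omega_foreground <= 0:
            raise ValueError("kappa and omegas must be positive")
        f = np.asarray(self.codon_frequencies, dtype=float)
        if f.shape != (len(CODONS),) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("codon frequencies must be a normalized 61-vector")
        self.codon_frequencies = f

    def omega_for(self, branch: str) -> float:
        return self.omega_foreground if branch == FOREGROUND_BRANCH else self.omega_background


def saturation_filter(ks: float, threshold: float = 2.5) -> str:
    """Gene filter on the synonymous rate: Ks = 0 and Ks > threshold (2.5,
    the saturation regime) are unreliable and dropped."""
    if ks == 0:
        return "drop_zero"
    if ks > threshold:
        return "drop_saturated"
    return "keep"


# ---------------------------------------------------------------------------
# Likelihood


def _codon_columns(alignment: MultiCodonAlignment) -> np.ndarray:
    """(4, n_usable) tip codon indices, quartet order; gap/N columns dropped."""
    try:
        rows = [alignment.row(sp) for sp in QUARTET_SPECIES]
    except ValueError as exc:
        raise DataError(f"alignment lacks a quartet species: {exc}") from exc
    width = len(rows[0])
    cols = []
    for i in range(0, width, 3):
        codons = [r[i : i + 3] for r in rows]
        if any("-" in c or "N" in c for c in codons):
            continue
        idx = []
        for c in codons:
            if c in STOP_CODONS:
                raise DataError(f"{alignment.gene_id}: in-frame stop codon {c} at column {i}")
            if c not in CODON_INDEX:
                raise DataError(f"{alignment.gene_id}: invalid codon {c!r} at column {i}")
            idx.append(CODON_INDEX[c])
        cols.append(idx)
    if not cols:
        raise DataError(f"{alignment.gene_id}: no usable codon columns")
    return np.asarray(cols, dtype=np.intp).T


def _compress_patterns(cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(cols, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def _pattern_log_likelihood(
    patterns: np.ndarray,
    counts: np.ndarray,
    tree: QuartetTree,
    params: CodonModelParams,
) -> float:
    """Felsenstein pruning on the quartet, vectorized over site patterns."""
    freqs = params.codon_frequencies
    p = {
        b: get_rate_model(params.kappa, params.omega_for(b), freqs).transition_matrix(
            tree.branch_lengths[b]
        )
        for b in BRANCHES
    }
    h, m, r, c = patterns
    # conditional likelihoods at the rodent ancestor node y
    l_y = p["mouse"][:, m] * p["rat"][:, r]  # (61, npat)
    msg = p["ancestor"] @ l_y
    # root at the human/cow junction x
    l_x = p["human"][:, h] * p["cow"][:, c] * msg
    site = freqs @ l_x
    return float(counts @ np.log(np.clip(site, 1e-300, None)))


def codon_log_likelihood(
    alignment: MultiCodonAlignment, tree: QuartetTree, params: CodonModelParams
) -> float:
    """Log-likelihood of a quartet codon alignment under the branch model."""
    patterns, counts = _compress_patterns(_codon_columns(alignment))
    return _pattern_log_likelihood(patterns, counts, tree, params)


# ---------------------------------------------------------------------------
# Model / Results


class CodonBranchModel:
    """Codon branch model for one quartet alignment.

    Parameters
    ----------
    alignment : MultiCodonAlignment
        Codon alignment containing human, mouse, rat and cow rows.
    frequencies : {"uniform", "f1x4"} or array
        Equilibrium codon frequencies: uniform over the 61 sense codons
        (default) or F1x4 from the alignment's nucleotide composition.

    Examples
    --------
    >>> model = CodonBranchModel(aln)                    # doctest: +SKIP
    >>> one = model.fit("one_ratio")                     # doctest: +SKIP
    >>> two = model.fit("two_ratios")                    # doctest: +SKIP
    >>> lrt(one, two).significant                        # doctest: +SKIP
    """

    MIN_CODONS = 10

    def __init__(self, alignment: MultiCodonAlignment, frequencies="uniform"):
        self.alignment = alignment
        cols = _codon_columns(alignment)
        if cols.shape[1] < self.MIN_CODONS:
            raise DataError(
                f"{alignment.gene_id}: {cols.shape[1]} usable codons "
                f"(minimum {self.MIN_CODONS})"
            )
        self.patterns, self.counts = _compress_patterns(cols)
        self.n_codons = int(self.counts.sum())
        if isinstance(frequencies, str):
            if frequencies == "uniform":
                self.freqs = uniform_frequencies()
            elif frequencies == "f1x4":
                self.freqs = f1x4_frequencies(
                    [alignment.row(sp).replace("-", "") for sp in QUARTET_SPECIES]
                )
            else:
                raise ValueError(f"unknown frequency model {frequencies!r}")
        else:
            self.freqs = np.asarray(frequencies, dtype=float)

    # -- parameter packing: theta = log(branch lengths[5], kappa, omega(s))

    def _unpack(self, theta: np.ndarray, model: str) -> tuple[QuartetTree, CodonModelParams]:
        vals = np.exp(theta)
        tree = QuartetTree(dict(zip(BRANCHES, vals[:5])))
        kappa = vals[5]
        w_bg = vals[6]
        w_fg = vals[7] if model == "two_ratios" else w_bg
        return tree, CodonModelParams(kappa, w_bg, w_fg, self.freqs)

    def loglike(self, theta: np.ndarray, model: str = "one_ratio") -> float:
        tree, params = self._unpack(np.asarray(theta, dtype=float), model)
        return _pattern_log_likelihood(self.patterns, self.counts, tree, params)

    def _data_informed_start(self) -> np.ndarray:
        """Branch lengths from three-point combinations of pairwise codon
        p-distances; kappa 2, omega 0.3."""
        h, m, r, c = self.patterns

        def dist(x, y):
            p_diff = float(self.counts @ (x != y)) / self.n_codons
            p_diff = min(p_diff, 0.95)
            return -np.log1p(-p_diff)  # rough multiple-hit correction

        d_hm, d_hr, d_hc = dist(h, m), dist(h, r), dist(h, c)
        d_mr, d_mc, d_rc = dist(m, r), dist(m, c), dist(r, c)
        t_m = (d_mr + d_hm - d_hr) / 2
        t_r = (d_mr + d_hr - d_hm) / 2
        h_y = (d_hm + d_hr - d_mr) / 2  # human to rodent node
        c_y = (d_mc + d_rc - d_mr) / 2
        t_h = (d_hc + h_y - c_y) / 2
        t_c = (d_hc + c_y - h_y) / 2
        t_anc = h_y - t_h
        bl = np.clip([t_h, t_m, t_r, t_c, t_anc], 5e-3, 5.0)
        return np.log(np.concatenate([bl, [2.0, 0.3, 0.3]]))

    def fit(
        self,
        model: str = "one_ratio",
        n_starts: int = 3,
        seed: int = 0,
        extra_starts: list[np.ndarray] | None = None,
    ) -> "BranchModelResults":
        """Maximize the log-likelihood by bounded quasi-Newton (L-BFGS-B in
        log-parameter space) from a data-informed start plus random restarts.

        ``extra_starts`` prepends additional full parameter vectors (used for
        warm-starting the two-ratios fit from the one-ratio optimum).
        """
        if model not in ("one_ratio", "two_ratios"):
            raise ValueError(f"unknown model {model!r}")
        ndim = 8 if model == "two_ratios" else 7
        base = self._data_informed_start()[:ndim]
        rng = np.random.default_rng(seed)
        starts = list(extra_starts or [])
        starts.append(base)
        for _ in range(max(0, n_starts - 1)):
            starts.append(base + rng.normal(0.0, 0.5, size=ndim))
        lo = np.log(
            [LENGTH_BOUNDS[0]] * 5 + [KAPPA_BOUNDS[0]] + [OMEGA_BOUNDS[0]] * (ndim - 6)
        )
        hi = np.log(
            [LENGTH_BOUNDS[1]] * 5 + [KAPPA_BOUNDS[1]] + [OMEGA_BOUNDS[1]] * (ndim - 6)
        )
        best = None
        converged = False
        for x0 in starts:
            res = optimize.minimize(
                lambda th: -self.loglike(th, model),
                np.clip(x0[:ndim], lo, hi),
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
                options={"maxiter": 500, "ftol": 1e-10},
            )
            if best is None or res.fun < best.fun - 1e-9:
                best = res
            converged = converged or bool(res.success)
        tree, params = self._unpack(best.x, model)
        return BranchModelResults(
            model=model,
            lnL=-float(best.fun),
            params=params,
            tree=tree,
            converged=converged,
            n_codons=self.n_codons,
            theta=best.x.copy(),
        )


@dataclass
class BranchModelResults:
    """Fitted branch model: estimates, derived per-branch rates, summary."""

    model: str
    lnL: float
    params: CodonModelParams
    tree: QuartetTree
    converged: bool
    n_codons: int
    theta: np.ndarray | None = None

    def _branch_rates(self) -> dict[str, tuple[float, float]]:
        """Per-branch (Ka, Ks): the branch length is split into synonymous
        and nonsynonymous flow at the branch's omega, then normalized per
        site with site proportions evaluated at omega = 1 (codeml-style)."""
        freqs = self.params.codon_frequencies
        rho1 = synonymous_flow_fraction(self.params.kappa, 1.0, freqs)
        s_sites = 3.0 * rho1
        n_sites = 3.0 - s_sites
        out = {}
        for b in BRANCHES:
            t = self.tree.branch_lengths[b]
            f_s = synonymous_flow_fraction(self.params.kappa, self.params.omega_for(b), freqs)
            out[b] = (t * (1.0 - f_s) / n_sites, t * f_s / s_sites)
        return out

    @property
    def ka_per_branch(self) -> dict[str, float]:
        return {b: ka for b, (ka, _) in self._branch_rates().items()}

    @property
    def ks_per_branch(self) -> dict[str, float]:
        return {b: ks for b, (_, ks) in self._branch_rates().items()}

    def summary(self) -> str:
        lines = [
            f"Codon branch model ({self.model.replace('_', '-')})",
            f"  tree: {self.tree.to_newick()}",
            f"  lnL = {self.lnL:.4f}   codons = {self.n_codons}   "
            f"converged = {self.converged}",
            f"  kappa = {self.params.kappa:.4f}",
            f"  omega (background) = {self.params.omega_background:.4f}",
        ]
        if self.model == "two_ratios":
            lines.append(
                f"  omega (foreground #1) = {self.params.omega_foreground:.4f}"
            )
        rates = self._branch_rates()
        lines.append("  branch            t        Ka        Ks")
        for b in BRANCHES:
            t = self.tree.branch_lengths[b]
            ka, ks = rates[b]
            tag = " #1" if b == FOREGROUND_BRANCH else ""
            lines.append(f"  {b:<12}{tag:<4}{t:8.4f}  {ka:8.4f}  {ks:8.4f}")
        return "\n".join(lines)


@dataclass
class LrtResult:
    """Likelihood-ratio decision between the one- and two-ratios models."""

    statistic: float
    significant: bool
    direction: str  # "elevated" | "reduced"
    p_value: float  # one-sided boundary-mixture p

    @property
    def threshold(self) -> float:
        return LRT_THRESHOLD


def lrt(one: BranchModelResults, two: BranchModelResults) -> LrtResult:
    """2*(lnL_two - lnL_one), clipped at zero; significant when >= 2.71.

    Direction reports whether the fitted foreground omega lies above or
    below the background omega.
    """
    if one.model != "one_ratio" or two.model != "two_ratios":
        raise ValueError("lrt expects (one_ratio results, two_ratios results)")
    statistic = max(0.0, 2.0 * (two.lnL - one.lnL))
    direction = (
        "elevated"
        if two.params.omega_foreground >= two.params.omega_background
        else "reduced"
    )
    p = 0.5 * float(stats.chi2.sf(statistic, df=1)) if statistic > 0 else 1.0
    return LrtResult(
        statistic=statistic,
        significant=statistic >= LRT_THRESHOLD,
        direction=direction,
        p_value=p,
    )


def lrt_critical_value(alpha: float = 0.05) -> float:
    """Critical value of the boundary-mixture null 1/2 delta_0 + 1/2 chi2_1:
    solves 0.5 * P(chi2_1 >= c) = alpha."""
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    return float(stats.chi2.ppf(1.0 - 2.0 * alpha, df=1))


def fit_branch_models(
    alignment: MultiCodonAlignment,
    frequencies="uniform",
    n_starts: int = 3,
    seed: int = 0,
) -> tuple[BranchModelResults, BranchModelResults, LrtResult]:
    """Fit both models (two-ratios warm-started at the one-ratio optimum,
    which guarantees the nesting inequality) and run the LRT."""
    cbm = CodonBranchModel(alignment, frequencies)
    one = cbm.fit("one_ratio", n_starts=n_starts, seed=seed)
    warm = np.concatenate([one.theta, [one.theta[-1]]])
    two = cbm.fit("two_ratios", n_starts=n_starts, seed=seed, extra_starts=[warm])
    return one, two, lrt(one, two)
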