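"""Triangulation of human-to-rodent-ancestor divergence.

With pairwise values for human-mouse (hs_mm), human-rat (hs_rn) and
mouse-rat (mm_rn), additivity of distances on the three-taxon star tree
places the mouse-rat ancestor at

    d(human, ancestor) = (d_hs_mm + d_hs_rn - d_mm_rn) / 2.

For percent identities the additive quantity is the divergence
d = 100 - identity; for Ka or Ks the rates are additive directly.  The
estimate is meaningful only when the two rodents are closer to each other
than either is to human; otherwise the gene is reported as not applicable
(alignment artifacts such as exon-usage changes produce such cases).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .io import GenePairRecord

logger = logging.getLogger("imprintdiv")


@dataclass(frozen=True)
class TriangulationInput:
    """The three pairwise values (identities in percent, or rates)."""

    hs_mm: float
    hs_rn: float
    mm_rn: float


@dataclass(frozen=True)
class TriangulationEstimate:
    hs_rodent: float | None
    applicable: bool
    reason: str = ""


def triangulate_identity(t: TriangulationInput) -> TriangulationEstimate:
    """Human-to-ancestor percent identity from the three pairwise identities.

    Applicable only when mm_rn exceeds both human-rodent identities.
    """
    for name in ("hs_mm", "hs_rn", "mm_rn"):
        v = getattr(t, name)
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name}={v} outside [0, 100]")
    if t.mm_rn <= t.hs_mm or t.mm_rn <= t.hs_rn:
        return TriangulationEstimate(
            None, False,
            "mouse-rat identity not above both human-rodent identities",
        )
    d_hs_mm, d_hs_rn, d_mm_rn = (100.0 - t.hs_mm, 100.0 - t.hs_rn, 100.0 - t.mm_rn)
    d_anc = (d_hs_mm + d_hs_rn - d_mm_rn) / 2.0
    return TriangulationEstimate(100.0 - d_anc, True)


def triangulate_rate(t: TriangulationInput) -> TriangulationEstimate:
    """Human-to-ancestor Ka or Ks from the three pairwise rates.

    Applicable only when the mouse-rat rate does not exceed either
    human-rodent rate.
    """
    for name in ("hs_mm", "hs_rn", "mm_rn"):
        if getattr(t, name) < 0:
            raise ValueError(f"{name} must be a non-negative rate")
    if t.mm_rn > t.hs_mm or t.mm_rn > t.hs_rn:
        return TriangulationEstimate(
            None, False, "mouse-rat rate exceeds a human-rodent rate"
        )
    return TriangulationEstimate((t.hs_mm + t.hs_rn - t.mm_rn) / 2.0, True)


_QUANTITIES = ("protein_identity", "cdna_identity", "ka", "ks")


@dataclass
class GeneTriangulation:
    """Per-gene ancestor estimates for the five reported quantities."""

    gene_id: str
    protein_identity: TriangulationEstimate | None = None
    cdna_identity: TriangulationEstimate | None = None
    ka: TriangulationEstimate | None = None
    ks: TriangulationEstimate | None = None

    @property
    def ka_ks(self) -> float | None:
        """Ka/Ks of the human-to-ancestor branch, from triangulated rates."""
        if (
            self.ka is not None and self.ka.applicable
            and self.ks is not None and self.ks.applicable
            and self.ks.hs_rodent and self.ks.hs_rodent > 0
        ):
            return self.ka.hs_rodent / self.ks.hs_rodent
        return None


@dataclass
class TriangulationTable:
    estimates: list[GeneTriangulation]
    n_skipped: int
    n_inapplicable: dict[str, int] = field(default_factory=dict)


def triangulate_table(pairs: list[GenePairRecord]) -> TriangulationTable:
    """Triangulate every gene that has all three rodent-relevant pairs.

    Genes missing any of human-mouse, human-rat or mouse-rat are skipped
    (logged); per-quantity inapplicability counts are accumulated so that
    genome-wide exclusion totals can be reported.
    """
    by_gene: dict[str, dict[frozenset, GenePairRecord]] = defaultdict(dict)
    for rec in pairs:
        by_gene[rec.gene_id][frozenset((rec.species_a, rec.species_b))] = rec

    keys = {
        "hs_mm": frozenset(("human", "mouse")),
        "hs_rn": frozenset(("human", "rat")),
        "mm_rn": frozenset(("mouse", "rat")),
    }
    out: list[GeneTriangulation] = []
    n_skipped = 0
    n_inapplicable = {q: 0 for q in _QUANTITIES}
    for gene_id, recs in sorted(by_gene.items()):
        if any(k not in recs for k in keys.values()):
            logger.info("triangulation: gene %s missing a species pair; skipped", gene_id)
            n_skipped += 1
            continue
        trio = {name: recs[k] for name, k in keys.items()}
        gt = GeneTriangulation(gene_id)
        for quantity in ("protein_identity", "cdna_identity"):
            vals = {n: getattr(r, quantity) for n, r in trio.items()}
            if any(v is None for v in vals.values()):
                continue
            est = triangulate_identity(TriangulationInput(**vals))
            setattr(gt, quantity, est)
            if not est.applicable:
                n_inapplicable[quantity] += 1
        for quantity in ("ka", "ks"):
            if any(r.ks_discarded for r in trio.values()):
                continue
            vals = {n: getattr(r, quantity) for n, r in trio.items()}
            if any(v is None for v in vals.values()):
                continue
            est = triangulate_rate(TriangulationInput(**vals))
            setattr(gt, quantity, est)
            if not est.applicable:
                n_inapplicable[quantity] += 1
        out.append(gt)
    return TriangulationTable(out, n_skipped, n_inapplicable)
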