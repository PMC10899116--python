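"""Tumor-level pattern quantification, IASLC grading and agreement metrics.

The tumor-level proportion of pattern j pools pixel counts over a tumor's
m slides:

    g_j = sum_i S_ij / sum_i sum_j S_ij            (j over the 6 patterns)

and the predominant pattern is P = argmax_j g_j.  IASLC grade: grade 1 for
lepidic-predominant tumors with < 20% combined high-grade patterns
(cribriform + micropapillary + solid), grade 2 for acinar- or
papillary-predominant tumors with < 20% high-grade, grade 3 for any tumor
with >= 20% high-grade patterns (or a high-grade predominant pattern).
Boundary comparisons use exact rational arithmetic on pixel counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .config import CLASS_NAMES, HIGH_GRADE_IDS, PATTERN_IDS, SEVERITY_ORDER
from .mask import LabelMask

__all__ = [
    "PatternComposition", "TumorGrade",
    "compute_proportions", "predominant_pattern", "iaslc_grade",
    "shannon_diversity", "dice_coefficient", "rater_agreement",
]


@dataclass
class PatternComposition:
    """Per-slide pixel counts S_ij and pooled tumor proportions g_j.

    ``counts`` is an (m, 6) integer array over the patterns in
    ``PATTERN_IDS`` order; proportions are exact Fractions of the pooled
    counts.  ``defined`` is False when no tumor pixel exists.
    """

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=np.int64))
        if self.counts.shape[1] != len(PATTERN_IDS):
            raise ValueError("counts must have one column per growth pattern")
        if (self.counts < 0).any():
            raise ValueError("pixel counts must be non-negative")

    @property
    def m(self) -> int:
        return self.counts.shape[0]

    @property
    def defined(self) -> bool:
        return bool(self.counts.sum() > 0)

    @property
    def pooled(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def g(self) -> dict:
        """Pattern name -> exact pooled proportion (Fraction)."""
        total = int(self.pooled.sum())
        if total == 0:
            raise ValueError("composition undefined: no tumor pixels")
        return {CLASS_NAMES[c]: Fraction(int(s), total)
                for c, s in zip(PATTERN_IDS, self.pooled)}

    @classmethod
    def from_proportions(cls, proportions: dict, denominator: int = 10 ** 6
                         ) -> "PatternComposition":
        """Build a single-slide composition from target proportions.

        Proportions are converted through ``Fraction(str(p))`` so decimal
        literals like 0.15 stay exact.
        """
        fracs = {k: Fraction(str(v)) for k, v in proportions.items()}
        if sum(fracs.values()) != 1:
            raise ValueError("proportions must sum to exactly 1")
        by_name = {CLASS_NAMES[c]: c for c in PATTERN_IDS}
        row = np.zeros(len(PATTERN_IDS), dtype=np.int64)
        for name, f in fracs.items():
            cid = by_name[name] if isinstance(name, str) else int(name)
            count = f * denominator
            if count.denominator != 1:
                raise ValueError(f"{name}: {f} not representable over "
                                 f"denominator {denominator}")
            row[PATTERN_IDS.index(cid)] = int(count)
        return cls(row[None, :])


@dataclass(frozen=True)
class TumorGrade:
    predominant: str
    grade: int
    high_grade_fraction: Fraction


def compute_proportions(masks) -> PatternComposition:
    """Exact per-slide pattern pixel counts from label masks (class 0 and
    any non-pattern label are excluded from the denominator)."""
    if not masks:
        raise ValueError("at least one mask is required")
    rows = []
    for m in masks:
        labels = m.labels if isinstance(m, LabelMask) else np.asarray(m)
        counts = np.bincount(labels.ravel(), minlength=7)
        rows.append([counts[c] for c in PATTERN_IDS])
    return PatternComposition(np.array(rows, dtype=np.int64))


def predominant_pattern(comp: PatternComposition) -> str:
    """Pattern with the highest pooled proportion; exact ties go to the
    higher-grade (clinically more aggressive) pattern."""
    if not comp.defined:
        raise ValueError("composition undefined: no tumor pixels")
    pooled = comp.pooled
    best = max(pooled)
    for cid in SEVERITY_ORDER:                    # most aggressive first
        if pooled[PATTERN_IDS.index(cid)] == best:
            return CLASS_NAMES[cid]
    raise AssertionError("unreachable")


def iaslc_grade(comp: PatternComposition) -> TumorGrade:
    """IASLC grade from the pooled composition (exact 20% boundary)."""
    if not comp.defined:
        raise ValueError("composition undefined: no tumor pixels")
    pooled = comp.pooled
    total = int(pooled.sum())
    high = Fraction(int(sum(pooled[PATTERN_IDS.index(c)] for c in HIGH_GRADE_IDS)),
                    total)
    pred = predominant_pattern(comp)
    if high >= Fraction(1, 5):
        grade = 3
    elif pred == "lepidic":
        grade = 1
    elif pred in ("acinar", "papillary"):
        grade = 2
    else:                       # high-grade predominant below the 20% cutoff
        grade = 3
    return TumorGrade(predominant=pred, grade=grade, high_grade_fraction=high)


def shannon_diversity(comp: PatternComposition) -> float:
    """Shannon index H = -sum g_j ln g_j over nonzero proportions (nats)."""
    if not comp.defined:
        raise ValueError("composition undefined: no tumor pixels")
    g = np.array([float(v) for v in comp.g.values()])
    g = g[g > 0]
    return float(-(g * np.log(g)).sum())


def dice_coefficient(pred, truth, class_id: int) -> float:
    """Dice overlap 2|A^B|/(|A|+|B|) of one class; 1.0 when both empty."""
    a = (pred.labels if isinstance(pred, LabelMask) else np.asarray(pred))
    b = (truth.labels if isinstance(truth, LabelMask) else np.asarray(truth))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    a = a == class_id
    b = b == class_id
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _cohen_kappa(r1, r2) -> Fraction:
    cats = sorted(set(r1) | set(r2))
    n = len(r1)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)), dtype=np.int64)
    for a, b in zip(r1, r2):
        table[idx[a], idx[b]] += 1
    po = Fraction(int(np.trace(table)), n)
    pe = Fraction(0)
    for i in range(len(cats)):
        pe += Fraction(int(table[i].sum()), n) * Fraction(int(table[:, i].sum()), n)
    if pe == 1:
        raise ZeroDivisionError("kappa undefined: chance agreement is 1")
    return (po - pe) / (1 - pe)


def _fleiss_kappa(ratings) -> Fraction:
    cats = sorted({c for row in ratings for c in row})
    n_items = len(ratings)
    r = len(ratings[0])
    counts = np.zeros((n_items, len(cats)), dtype=np.int64)
    idx = {c: i for i, c in enumerate(cats)}
    for i, row in enumerate(ratings):
        for c in row:
            counts[i, idx[c]] += 1
    p_bar = Fraction(0)
    for i in range(n_items):
        p_bar += Fraction(int((counts[i] ** 2).sum()) - r, r * (r - 1))
    p_bar /= n_items
    pe = Fraction(0)
    for j in range(len(cats)):
        pj = Fraction(int(counts[:, j].sum()), n_items * r)
        pe += pj * pj
    if pe == 1:
        raise ZeroDivisionError("kappa undefined: chance agreement is 1")
    return (p_bar - pe) / (1 - pe)


def rater_agreement(ratings) -> dict:
    """Agreement statistics for per-case categorical calls.

    ``ratings`` is a sequence of per-case tuples, one call per rater.
    Returns percent agreement (mean pairwise), Cohen's kappa for two raters
    or Fleiss' kappa for three or more, computed with exact fractions.  When
    every call is the same single category, kappa is undefined and returned
    as None with ``kappa_defined`` False.
    """
    ratings = [tuple(row) for row in ratings]
    if len(ratings) < 2:
        raise ValueError("at least two cases are required")
    n_raters = len(ratings[0])
    if n_raters < 2 or any(len(r) != n_raters for r in ratings):
        raise ValueError("every case needs the same >=2 rater calls")

    pairs = [(i, j) for i in range(n_raters) for j in range(i + 1, n_raters)]
    agree = Fraction(0)
    for i, j in pairs:
        agree += Fraction(sum(r[i] == r[j] for r in ratings), len(ratings))
    percent = float(agree / len(pairs)) * 100.0

    cats = {c for row in ratings for c in row}
    if len(cats) < 2:
        return {"percent_agreement": percent, "kappa": None,
                "kappa_defined": False}
    if n_raters == 2:
        kappa = _cohen_kappa([r[0] for r in ratings], [r[1] for r in ratings])
    else:
        kappa = _fleiss_kappa(ratings)
    return {"percent_agreement": percent, "kappa": float(kappa),
            "kappa_defined": True}
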