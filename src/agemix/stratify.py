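"""Stratum definitions over case records.

Covers the ER-percent category scheme (negative / borderline / low /
intermediate / high, with a nested very-high flag at >= 95%), binary
clinical ER cut points, expression standardization and quartiles,
subtype filtering, and tumor-characteristic groupings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np

from .errors import AgemixWarning, DegenerateDataError, TieWarning
from .io import CaseRecord

__all__ = [
    "StratumDefinition",
    "ERAssignment",
    "ER_CATEGORIES",
    "assign_er_category",
    "assign_clinical_er",
    "standardize_esr1",
    "assign_quartiles",
    "filter_pam50",
    "normalize_pam50_label",
    "assign_tumor_characteristic_strata",
    "group_records",
    "VALID_PAM50",
]

ER_CATEGORIES = ("negative", "borderline", "low", "intermediate", "high")


@dataclass(frozen=True)
class StratumDefinition:
    """Named predicate over case records; ``overlapping`` marks nested
    subanalysis strata (e.g. ER >= 95% inside >= 80%)."""

    name: str
    predicate: Callable[[CaseRecord], bool]
    overlapping: bool = False


class ERAssignment(NamedTuple):
    category: str
    very_high: bool


def assign_er_category(er_percent: float) -> ERAssignment:
    """Primary ER-percent partition plus the nested very-high flag.

    < 1 -> negative; 1-<10 -> borderline; 10-<40 -> low; 40-<80 ->
    intermediate; >= 80 -> high. ``very_high`` is set at >= 95 (nested
    within high, not a sixth partition cell).
    """
    if er_percent is None or not np.isfinite(er_percent):
        raise ValueError("er_percent must be a finite number")
    if not (0.0 <= er_percent <= 100.0):
        raise ValueError(f"er_percent {er_percent} outside [0, 100]")
    if er_percent < 1:
        cat = "negative"
    elif er_percent < 10:
        cat = "borderline"
    elif er_percent < 40:
        cat = "low"
    elif er_percent < 80:
        cat = "intermediate"
    else:
        cat = "high"
    return ERAssignment(cat, er_percent >= 95)


def assign_clinical_er(er_percent: float, cutpoint: int) -> str:
    """Binary clinical ER status at the 1% or 10% cut point (closed at
    the boundary)."""
    if cutpoint not in (1, 10):
        raise ValueError(f"cutpoint must be 1 or 10, got {cutpoint}")
    if er_percent is None or not (0.0 <= er_percent <= 100.0):
        raise ValueError(f"er_percent {er_percent} outside [0, 100]")
    return "positive" if er_percent >= cutpoint else "negative"


def standardize_esr1(values) -> np.ndarray:
    """Median-center, then rescale to sample mean 0 and variance 1.

    The composed transform is affine, so downstream quartile assignment
    is invariant to the centering order.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise DegenerateDataError("need >= 2 non-missing expression values")
    centered = x - np.median(x[finite])
    mu = centered[finite].mean()
    sd = centered[finite].std()
    if sd <= 0:
        raise DegenerateDataError("zero spread: cannot standardize")
    out = (centered - mu) / sd
    return out


def assign_quartiles(values) -> np.ndarray:
    """Quartile labels Q1 (lowest) .. Q4 (highest) by rank.

    Group sizes differ by at most one; when ``n`` is not divisible by 4
    the remainder goes to the top quartiles first (n = 1965 gives Q4 =
    492 and Q1-Q3 = 491). Ties are broken by stable input order, with a
    warning when a tied value spans a quartile boundary.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise DegenerateDataError("need >= 4 values for quartiles")
    order = np.argsort(x, kind="stable")
    base, rem = divmod(n, 4)
    # remainder to the top quartiles first: Q4, then Q3, ...
    sizes = [base + (1 if q > 4 - rem else 0) for q in (1, 2, 3, 4)]
    labels = np.empty(n, dtype=object)
    start = 0
    boundaries = []
    for q, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = f"Q{q}"
        if start + size < n:
            boundaries.append((x[order[start + size - 1]], x[order[start + size]]))
        start += size
    if any(a == b for a, b in boundaries):
        warnings.warn(
            "tied values span a quartile boundary; assignment follows "
            "stable input order",
            TieWarning,
            stacklevel=2,
        )
    return labels


VALID_PAM50 = ("LumA", "LumB", "Her2", "Basal")

_PAM50_ALIASES = {
    "luma": "LumA",
    "luminal a": "LumA",
    "luminala": "LumA",
    "lumb": "LumB",
    "luminal b": "LumB",
    "luminalb": "LumB",
    "her2": "Her2",
    "her2-enriched": "Her2",
    "her2e": "Her2",
    "her2 enriched": "Her2",
    "basal": "Basal",
    "basal-like": "Basal",
    "basallike": "Basal",
    "basal like": "Basal",
    "normal": "Normal",
    "normal-like": "Normal",
    "normallike": "Normal",
    "normal like": "Normal",
}


def normalize_pam50_label(label: Optional[str]) -> Optional[str]:
    """Canonicalize a subtype label via the alias table, or None."""
    if label is None:
        return None
    return _PAM50_ALIASES.get(str(label).strip().lower())


def filter_pam50(records: Sequence[CaseRecord]):
    """Keep the four intrinsic subtypes; drop normal-like, missing, and
    unrecognized labels (counts per reason are reported in a warning).

    Returns records with normalized ``pam50`` labels; idempotent.
    """
    kept = []
    dropped = {"normal_like": 0, "missing": 0, "unrecognized": 0}
    for rec in records:
        canon = normalize_pam50_label(rec.pam50)
        if rec.pam50 is None:
            dropped["missing"] += 1
        elif canon == "Normal":
            dropped["normal_like"] += 1
        elif canon is None:
            dropped["unrecognized"] += 1
        else:
            if canon != rec.pam50:
                rec = CaseRecord(**{**rec.__dict__, "pam50": canon})
            kept.append(rec)
    n_dropped = sum(dropped.values())
    if n_dropped:
        warnings.warn(
            f"filter_pam50 dropped {n_dropped} record(s): {dropped}",
            AgemixWarning,
            stacklevel=2,
        )
    if not kept:
        warnings.warn(
            "filter_pam50: no records remain", AgemixWarning, stacklevel=2
        )
    return kept


def assign_tumor_characteristic_strata(
    records: Sequence[CaseRecord],
    scheme: str,
    *,
    size_cut: float = 2.0,
    node_groups=("negative", "1", "2+"),
):
    """Label records by a tumor-characteristic scheme.

    ``grade`` -> {1, 2, 3}; ``size`` -> small/large at ``size_cut`` cm
    (default 2); ``nodes`` -> negative / 1 / 2+. Cut points are
    configurable. Records with unknown or missing values are excluded
    with a warning.
    """
    if scheme not in ("grade", "size", "nodes"):
        raise ValueError(f"unknown scheme {scheme!r}")
    labels = []
    excluded = 0
    for rec in records:
        label = None
        if scheme == "grade":
            if rec.grade in (1, 2, 3):
                label = f"grade{rec.grade}"
        elif scheme == "size":
            if rec.tumor_size is not None and np.isfinite(rec.tumor_size):
                label = "small" if rec.tumor_size < size_cut else "large"
        else:  # nodes
            label = _node_label(rec.node_status, node_groups)
        if label is None:
            excluded += 1
        labels.append(label)
    if excluded:
        warnings.warn(
            f"{excluded} record(s) excluded from {scheme} strata "
            "(unknown or missing values)",
            AgemixWarning,
            stacklevel=2,
        )
    return labels


def _node_label(status, node_groups):
    if status is None:
        return None
    s = str(status).strip().lower()
    if s in ("negative", "neg", "0", "node-negative"):
        return node_groups[0]
    try:
        count = int(float(s))
    except ValueError:
        return None
    if count <= 0:
        return node_groups[0]
    if count == 1:
        return node_groups[1]
    return node_groups[2]


def group_records(records: Sequence[CaseRecord], key: Callable):
    """Group records by ``key(record)``; None keys are excluded.

    Returns an insertion-ordered dict label -> list of records.
    """
    out = {}
    for rec in records:
        label = key(rec)
        if label is None:
            continue
        out.setdefault(label, []).append(rec)
    return out
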