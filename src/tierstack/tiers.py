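"""Four-tier annual usage class schemes and threshold binarization.

A scheme partitions a non-negative annual count (inpatient bed days or ED
visits) into four mutually exclusive tiers: tier 0 below the first threshold,
tiers 1 and 2 the half-open bands between consecutive thresholds, and tier 3
unbounded above the last threshold.  The same thresholds define three binary
"count >= threshold" tasks whose fitted probabilities feed the stacking
ensemble as meta-features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InvalidSpecError

__all__ = ["UsageClassScheme", "LOS_SCHEME", "ED_SCHEME", "assign_class", "binarize", "scheme_by_name"]


@dataclass(frozen=True)
class UsageClassScheme:
    """Ordered thresholds defining 4 usage tiers and 3 binary exceedance tasks.

    Parameters
    ----------
    name : str
        Outcome name, conventionally ``"LOS"`` (inpatient bed days) or
        ``"ED"`` (emergency-department visits).
    thresholds : tuple of int
        Strictly increasing positive integers ``(t1, t2, t3)``.  Tier k
        (k = 1, 2) covers ``[t_k, t_{k+1})``; tier 3 is ``>= t3``; tier 0 is
        ``[0, t1)``.
    class_labels : tuple of str
        Human-readable tier names, derived from the thresholds by default.
    """

    name: str
    thresholds: tuple[int, int, int]
    class_labels: tuple[str, str, str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        t = tuple(int(x) for x in self.thresholds)
        if len(t) != 3:
            raise InvalidSpecError(f"exactly 3 thresholds required, got {len(t)}")
        if t[0] <= 0 or not (t[0] < t[1] < t[2]):
            raise InvalidSpecError(f"thresholds must be positive and strictly increasing, got {t}")
        object.__setattr__(self, "thresholds", t)
        if self.class_labels is None:
            labels = (
                f"<{t[0]}",
                f"{t[0]}-{t[1] - 1}",
                f"{t[1]}-{t[2] - 1}",
                f">={t[2]}",
            )
            object.__setattr__(self, "class_labels", labels)
        elif len(self.class_labels) != 4:
            raise InvalidSpecError("exactly 4 class labels required")

    def to_dict(self) -> dict:
        return {"name": self.name, "thresholds": list(self.thresholds), "class_labels": list(self.class_labels)}

    @classmethod
    def from_dict(cls, d: dict) -> "UsageClassScheme":
        labels = d.get("class_labels")
        return cls(
            name=d["name"],
            thresholds=tuple(d["thresholds"]),
            class_labels=tuple(labels) if labels else None,
        )


#: Inpatient length-of-stay tiers: <7, 7-13, 14-29, >=30 bed days per year.
LOS_SCHEME = UsageClassScheme(name="LOS", thresholds=(7, 14, 30))

#: Emergency-department tiers: <3, 3-4, 5-9, >=10 visits per year.
ED_SCHEME = UsageClassScheme(name="ED", thresholds=(3, 5, 10))

_SCHEMES = {"LOS": LOS_SCHEME, "ED": ED_SCHEME}


def scheme_by_name(name: str) -> UsageClassScheme:
    """Look up a packaged scheme by its (case-insensitive) outcome name."""
    try:
        return _SCHEMES[name.upper()]
    except KeyError:
        raise DomainError(f"unknown scheme {name!r}; packaged schemes: {sorted(_SCHEMES)}") from None


def assign_class(count, scheme: UsageClassScheme):
    """Map annual usage count(s) to tier indices in {0, 1, 2, 3}.

    Accepts a scalar or array-like of non-negative integers and returns the
    unique tier whose half-open interval contains each count.
    """
    arr = np.asarray(count)
    if np.any(arr < 0):
        raise DomainError("usage counts must be non-negative")
    tiers = np.searchsorted(np.asarray(scheme.thresholds), arr, side="right")
    if np.isscalar(count) or arr.ndim == 0:
        return int(tiers)
    return tiers.astype(np.int64)


def binarize(count, threshold_index: int, scheme: UsageClassScheme):
    """Binary exceedance label: 1 iff count >= thresholds[threshold_index].

    ``threshold_index`` is 1-based in {1, 2, 3}, matching the tier index the
    threshold opens: ``binarize(c, j) == 1 <=> assign_class(c) >= j``.
    """
    if threshold_index not in (1, 2, 3):
        raise DomainError(f"threshold_index must be in {{1,2,3}}, got {threshold_index}")
    arr = np.asarray(count)
    if np.any(arr < 0):
        raise DomainError("usage counts must be non-negative")
    out = (arr >= scheme.thresholds[threshold_index - 1]).astype(np.int64)
    if np.isscalar(count) or arr.ndim == 0:
        return int(out)
    return out
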