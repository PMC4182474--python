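"""End-stage histology indices: Ki67 labelling, TUNEL area fraction,
and the proliferation/apoptosis Growth Index.

Counts are inputs here — cell detection from raw micrographs is out of
scope.  The Ki67 labelling index averages the positive fraction over
(typically five) manually selected hotspot fields; apoptosis is
quantified as the fraction of pixels whose staining intensity exceeds a
stored threshold; the Growth Index is the mean over animals of each
animal's proliferation/apoptosis ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class HotspotCounts:
    positive: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("hotspot total must be positive")
        if not 0 <= self.positive <= self.total:
            raise ValueError("positive count must lie in [0, total]")

    @property
    def fraction(self) -> float:
        return self.positive / self.total


@dataclass(frozen=True)
class AreaFractionResult:
    fraction: float
    threshold: float


def ki67_index(hotspots: Sequence) -> float:
    """Mean positive fraction over hotspot fields.

    ``hotspots`` may contain :class:`HotspotCounts` or (positive, total)
    pairs.
    """
    if len(hotspots) == 0:
        raise ValueError("need at least one hotspot")
    fracs = []
    for h in hotspots:
        if not isinstance(h, HotspotCounts):
            h = HotspotCounts(*h)
        fracs.append(h.fraction)
    return float(np.mean(fracs))


def area_fraction(image: np.ndarray, threshold: float) -> AreaFractionResult:
    """Fraction of pixels strictly above ``threshold``.

    Ties at the threshold count as negative — the convention is strict
    ``>`` since the original microscope software's tie handling is not
    knowable.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image is empty")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    frac = float(np.count_nonzero(image > threshold) / image.size)
    return AreaFractionResult(fraction=frac, threshold=float(threshold))


def growth_index(proliferation: float, apoptosis: float) -> float:
    """Per-animal ratio of proliferation to apoptosis indices."""
    if apoptosis <= 0:
        raise ValueError("apoptosis index must be positive "
                         "(ratio undefined at zero)")
    return proliferation / apoptosis


def group_growth_index(ratios: Iterable[float],
                       method: str = "mean_of_ratios") -> float:
    """Group-level Growth Index.

    ``mean_of_ratios`` (default) averages per-animal ratios;
    ``ratio_of_means`` is exposed as an alternative for pairs of
    (proliferation, apoptosis) tuples.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("no animals supplied")
    if method == "mean_of_ratios":
        return float(np.mean(ratios))
    if method == "ratio_of_means":
        prol, apop = zip(*ratios)
        mean_apop = float(np.mean(apop))
        if mean_apop <= 0:
            raise ValueError("mean apoptosis index must be positive")
        return float(np.mean(prol)) / mean_apop
    raise ValueError(f"unknown method {method!r}")
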