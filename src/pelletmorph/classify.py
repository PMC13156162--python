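"""Inner-architecture classification of pellets (classes I–IV).

Coagulative pellets fall into growth-related architecture classes: class I
grows uniformly outward from one centred spore agglomerate; class II forms by
attachment of multiple spore agglomerates; class III arises from mature
pellets or fragments loosely entangled by hyphae, often with irregular,
non-spherical shapes; class IV is a provisional, process-oriented label for
shear-broken fragments.

The classifier is a deterministic rule cascade over per-pellet 3D metrics —
the spore-cluster count and the solid fraction at the mass centre are the
indicators, with envelope sphericity as the shape criterion.  The thresholds
are declared, configurable defaults calibrated on synthetic archetypes; they
are indicators turned into an explicit rule, not a literature-given cutoff.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal

from .tomo3d import PelletMetrics3D

__all__ = ["ClassRule", "classify_pellet", "class_shares", "UNCLASSIFIED"]

UNCLASSIFIED = "unclassified"
_CLASS_ORDER = ["I", "II", "III", "IV"]


@dataclass(frozen=True)
class ClassRule:
    """Thresholds of the classification cascade.

    ``max_clusters_class_I``: spore-cluster count up to which a compact
    pellet counts as grown from a single agglomeration event (seed pellets
    called mainly class I carry ~3 clusters on average, so 3 is the default).
    ``centre_fraction_loose_threshold``: below this solid fraction at the
    mass centre the pellet is considered loosely entangled (class III).
    ``sphericity_threshold``: envelope sphericity below which the shape is
    called irregular (class III).
    ``fragment_flag_source``: whether the class IV flag comes from the
    simulator event log (ground truth) or from shape heuristics.
    """

    max_clusters_class_I: int = 3
    centre_fraction_loose_threshold: float = 0.05
    sphericity_threshold: float = 0.6
    fragment_flag_source: Literal["event_log", "shape"] = "event_log"

    def __post_init__(self) -> None:
        if self.max_clusters_class_I < 1:
            raise ValueError("max_clusters_class_I must be >= 1")
        if not 0 <= self.centre_fraction_loose_threshold <= 1:
            raise ValueError("centre_fraction_loose_threshold must be in [0, 1]")
        if not 0 < self.sphericity_threshold <= 1:
            raise ValueError("sphericity_threshold must be in (0, 1]")


def classify_pellet(
    m: PelletMetrics3D,
    sphericity: float | None = None,
    fragment: bool = False,
    rule: ClassRule | None = None,
) -> str:
    """Assign one pellet its inner-architecture class.

    Cascade: IV if fragment-flagged; else III if the shape is irregular
    (sphericity below threshold) or the centre is loose (centre solid
    fraction below threshold); else I if the spore-cluster count is at most
    ``max_clusters_class_I``; else II.  A missing cluster count yields
    ``"unclassified"`` rather than a guess.
    """
    rule = rule or ClassRule()
    if fragment:
        return "IV"
    sph = sphericity if sphericity is not None else m.sphericity
    if sph is not None and sph == sph and sph < rule.sphericity_threshold:
        return "III"
    if m.centre_solid_fraction < rule.centre_fraction_loose_threshold:
        return "III"
    if m.n_spore_clusters is None:
        return UNCLASSIFIED
    if m.n_spore_clusters <= rule.max_clusters_class_I:
        return "I"
    return "II"


def class_shares(classes: Iterable[str]) -> tuple[dict[str, float], str]:
    """Population class shares and the main (most frequent) class.

    Shares are over classified pellets only and sum to 1; ties between
    classes break toward the lower class number.  Raises when every pellet is
    unclassified.
    """
    counts = Counter(c for c in classes if c in _CLASS_ORDER)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no classified pellets")
    shares = {c: counts.get(c, 0) / total for c in _CLASS_ORDER if counts.get(c, 0)}
    main = max(shares, key=lambda c: (shares[c], -_CLASS_ORDER.index(c)))
    return shares, main
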