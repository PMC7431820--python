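"""Core record types shared across the package.

The unit of analysis throughout is the twin *pair*: up to four methylation
measurements (two co-twins at two occasions roughly a decade apart) modelled
jointly as one draw from a structured 4-variate normal.  Slots are ordered

    (twin1 @ occasion 1, twin1 @ occasion 2, twin2 @ occasion 1, twin2 @ occasion 2)

and an observed-mask marks which slots carry data; pairs with a twin measured
at a single occasion contribute the marginal density of their observed slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical slot order: (twin, occasion) for each of the four positions.
SLOT_ORDER: tuple[tuple[int, int], ...] = ((1, 1), (1, 2), (2, 1), (2, 2))

#: Occasion (1 or 2) of each slot.
SLOT_OCCASION = np.array([1, 2, 1, 2])

ZYGOSITIES = ("MZ", "DZ")


class RecordError(ValueError):
    """Raised when a pair record violates its structural invariants."""


@dataclass
class TwinPairRecord:
    """One twin pair's observations at up to two occasions, plus covariates.

    Parameters
    ----------
    pair_id : str
        Unique pair identifier.
    zygosity : {"MZ", "DZ"}
    country : {0, 1}
        Cohort indicator (0 = reference cohort, e.g. Sweden; 1 = scaled
        cohort, e.g. Denmark).  Both twins share it.
    sex : {0, 1}
        0 = male, 1 = female; same-sex pairs only.
    age_t1, age_t2 : float
        Ages in years at the two measurement occasions (twins share ages).
    y : ndarray, shape (4,)
        Observations in slot order; NaN where unobserved.
    mask : ndarray of bool, shape (4,)
        True where the slot is observed.
    """

    pair_id: str
    zygosity: str
    country: int
    sex: int
    age_t1: float
    age_t2: float
    y: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (4,):
            raise RecordError(f"pair {self.pair_id}: y must have length 4")
        if self.mask is None:
            self.mask = ~np.isnan(self.y)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (4,):
            raise RecordError(f"pair {self.pair_id}: mask must have length 4")
        if self.zygosity not in ZYGOSITIES:
            raise RecordError(
                f"pair {self.pair_id}: zygosity must be MZ or DZ, got {self.zygosity!r}"
            )
        if self.country not in (0, 1):
            raise RecordError(f"pair {self.pair_id}: country must be 0 or 1")
        if self.sex not in (0, 1):
            raise RecordError(f"pair {self.pair_id}: sex must be 0 or 1")
        if not self.mask.any():
            raise RecordError(f"pair {self.pair_id}: at least one slot must be observed")
        if np.isnan(self.y[self.mask]).any():
            raise RecordError(f"pair {self.pair_id}: observed slots contain NaN")

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def age_at_slot(self, slot: int) -> float:
        return self.age_t1 if SLOT_OCCASION[slot] == 1 else self.age_t2


ISLAND_RELATIONS = (
    "Island",
    "North Shore",
    "South Shore",
    "North Shelf",
    "South Shelf",
    "Open Seas",
)

SET_NAMES = ("AgingI", "AgingII", "Hannum", "Horvath", "Levine", "Zhang", "PCGT")


@dataclass
class SiteAnnotation:
    """CpG annotation: position relative to a CpG island plus set memberships."""

    site_id: str
    island_relation: str = "Open Seas"
    set_memberships: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.island_relation:
            self.island_relation = "Open Seas"
        if self.island_relation not in ISLAND_RELATIONS:
            raise RecordError(
                f"site {self.site_id}: unknown island relation {self.island_relation!r}"
            )
        self.set_memberships = frozenset(self.set_memberships)
        unknown = self.set_memberships - set(SET_NAMES)
        if unknown:
            raise RecordError(f"site {self.site_id}: unknown set names {sorted(unknown)}")
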