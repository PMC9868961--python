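"""Core record types for guide/target-site datasets.

A dataset pairs sgRNA guides (17-20 nt) with candidate genomic sites:
a protospacer of matched length, a 3-nt PAM immediately 3' of it, and a
window of flanking genomic context. Each site carries a binary label
(1 = on-target, the intended cleavage site; 0 = off-target). Coordinates
are 0-based half-open internally; minus-strand sites are stored already
reverse-complemented into protospacer orientation, so ``strand`` is
metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

GUIDE_MIN_LEN = 17
GUIDE_MAX_LEN = 20
PAM_LEN = 3
#: Minimum flanking-context window considered "full length" (nt).
CONTEXT_LEN = 223

_DNA = set("ACGT")
_DNA_N = set("ACGTN")


class ValidationError(ValueError):
    """A record violates a dataset invariant."""


def _check_alphabet(seq: str, allowed: set, what: str) -> None:
    bad = set(seq) - allowed
    if bad:
        raise ValidationError(f"{what} contains non-{''.join(sorted(allowed))} symbols: {sorted(bad)}")


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA. ``sequence`` is the DNA transliteration (U -> T)."""

    guide_id: str
    sequence: str
    crop: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))
        if not (GUIDE_MIN_LEN <= len(self.sequence) <= GUIDE_MAX_LEN):
            raise ValidationError(
                f"guide {self.guide_id!r}: length {len(self.sequence)} outside "
                f"[{GUIDE_MIN_LEN}, {GUIDE_MAX_LEN}]"
            )
        _check_alphabet(self.sequence, _DNA, f"guide {self.guide_id!r}")


@dataclass(frozen=True)
class TargetSiteRecord:
    """A candidate genomic site linked to a guide.

    ``protospacer_start`` locates the protospacer within ``context``
    (0-based); ``context[protospacer_start : protospacer_start + len(protospacer)
    + 3]`` must equal ``protospacer + pam``. Ambiguous bases (N) are
    permitted only in the context flanks, never in protospacer or PAM.
    """

    site_id: str
    guide_id: str
    protospacer: str
    pam: str
    context: str
    label: int
    protospacer_start: int = 0
    strand: str = "+"
    source: str = ""

    def __post_init__(self):
        for attr in ("protospacer", "pam", "context"):
            object.__setattr__(self, attr, getattr(self, attr).upper())
        if self.label not in (0, 1):
            raise ValidationError(f"site {self.site_id!r}: label {self.label!r} not in {{0, 1}}")
        if len(self.pam) != PAM_LEN:
            raise ValidationError(f"site {self.site_id!r}: PAM length {len(self.pam)} != {PAM_LEN}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"site {self.site_id!r}: strand {self.strand!r}")
        _check_alphabet(self.protospacer, _DNA, f"site {self.site_id!r} protospacer")
        _check_alphabet(self.pam, _DNA, f"site {self.site_id!r} PAM")
        _check_alphabet(self.context, _DNA_N, f"site {self.site_id!r} context")
        lo, hi = self.protospacer_start, self.protospacer_start + len(self.protospacer) + PAM_LEN
        if lo < 0 or hi > len(self.context) or self.context[lo:hi] != self.protospacer + self.pam:
            raise ValidationError(
                f"site {self.site_id!r}: protospacer+PAM not found in context at offset "
                f"{self.protospacer_start}"
            )

    @property
    def protospacer_end(self) -> int:
        """0-based offset of the first PAM base within the context."""
        return self.protospacer_start + len(self.protospacer)

    @property
    def context_is_full(self) -> bool:
        return len(self.context) >= CONTEXT_LEN


@dataclass
class LabeledDataset:
    """Guides, labeled sites, and (optionally) their feature matrix.

    ``features`` rows are indexed by site_id in site order;
    ``split_assignment`` maps site_id -> "train" | "test".
    """

    guides: list = field(default_factory=list)
    sites: list = field(default_factory=list)
    features: Optional[pd.DataFrame] = None
    split_assignment: Optional[dict] = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        gids = [g.guide_id for g in self.guides]
        if len(gids) != len(set(gids)):
            raise ValidationError("duplicate guide_id in dataset")
        sids = [s.site_id for s in self.sites]
        if len(sids) != len(set(sids)):
            raise ValidationError("duplicate site_id in dataset")
        known = set(gids)
        for s in self.sites:
            if s.guide_id not in known:
                raise ValidationError(f"site {s.site_id!r} references unknown guide {s.guide_id!r}")
        if self.features is not None and len(self.features) != len(self.sites):
            raise ValidationError(
                f"feature matrix has {len(self.features)} rows for {len(self.sites)} sites"
            )

    def guide_for(self, site: TargetSiteRecord) -> GuideRecord:
        return self._guide_index()[site.guide_id]

    def _guide_index(self) -> dict:
        return {g.guide_id: g for g in self.guides}

    @property
    def site_ids(self) -> list:
        return [s.site_id for s in self.sites]

    @property
    def labels(self) -> pd.Series:
        return pd.Series([s.label for s in self.sites], index=self.site_ids, name="label")

    def class_counts(self) -> dict:
        labs = [s.label for s in self.sites]
        return {1: labs.count(1), 0: labs.count(0)}

    def __len__(self) -> int:
        return len(self.sites)
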