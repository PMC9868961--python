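"""Pairwise sgRNA/protospacer alignment with bulge support.

The guide (as DNA, U transliterated to T) is aligned globally to the
candidate protospacer with a linear gap penalty, so 1-nt RNA or DNA
bulges appear as gaps. Each alignment column is classified by the kind
of pairing:

* MATCH — identical bases;
* RR / YY / TV — purine-purine, pyrimidine-pyrimidine, or
  purine<->pyrimidine (transversion) mismatch;
* RNA_BULGE — unpaired guide base (gap in the site row);
* DNA_BULGE — unpaired site base (gap in the guide row).

Wobble pairing (rG:dT or rU:dG with the target strand; in
protospacer-strand coordinates guide G over site A, or guide T over
site C) is tolerated by RNA:DNA hybrids and is flagged on top of the
column's RR/YY class, so wobble columns count in both wobble_total and
their rr/yy totals.

Guide positions are numbered 1 at the PAM-distal (5') end; the seed
region "positions 17-20" means the four PAM-proximal bases, whatever
the guide length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Tuple

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_DNA = frozenset("ACGT")
GAP = "-"

#: Seed-region width (PAM-proximal positions counted by mismatches_17_20).
SEED_WIDTH = 4


class PairClass(Enum):
    MATCH = "match"
    RR = "rr"
    YY = "yy"
    TV = "tv"
    RNA_BULGE = "rna_bulge"
    DNA_BULGE = "dna_bulge"


MISMATCH_CLASSES = (PairClass.RR, PairClass.YY, PairClass.TV)


@dataclass(frozen=True)
class Scoring:
    """Linear-gap global alignment scoring triple."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


def classify_pair(guide_base: str, site_base: str) -> Tuple[PairClass, bool]:
    """Classify one alignment column; returns (class, wobble_flag)."""
    g, s = guide_base.upper(), site_base.upper()
    if g == GAP and s == GAP:
        raise ValueError("alignment column with two gaps")
    if s == GAP:
        return PairClass.RNA_BULGE, False
    if g == GAP:
        return PairClass.DNA_BULGE, False
    if g not in _DNA or s not in _DNA:
        raise ValueError(f"non-ACGT bases in column ({g!r}, {s!r})")
    if g == s:
        return PairClass.MATCH, False
    wobble = (g, s) in (("G", "A"), ("T", "C"))
    if g in _PURINES and s in _PURINES:
        return PairClass.RR, wobble
    if g in _PYRIMIDINES and s in _PYRIMIDINES:
        return PairClass.YY, wobble
    return PairClass.TV, False


@dataclass
class GuideTargetAlignment:
    """A scored global alignment plus per-column classes and summary counts."""

    aligned_guide: str
    aligned_site: str
    score: float
    scoring: Scoring = field(default_factory=Scoring)
    columns: list = field(default_factory=list)
    wobble_flags: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.aligned_guide) != len(self.aligned_site):
            raise ValueError("aligned strings differ in length")
        if not self.columns:
            classified = [
                classify_pair(g, s) for g, s in zip(self.aligned_guide, self.aligned_site)
            ]
            self.columns = [c for c, _ in classified]
            self.wobble_flags = [w for _, w in classified]

    @property
    def guide_length(self) -> int:
        return sum(1 for c in self.aligned_guide if c != GAP)

    def guide_positions(self) -> list:
        """Per-column guide position (1 = PAM-distal), None on DNA bulges."""
        pos, out = 0, []
        for c in self.aligned_guide:
            if c == GAP:
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out

    @property
    def counts(self) -> dict:
        n = {
            "mismatches": sum(1 for c in self.columns if c in MISMATCH_CLASSES),
            "rna_bulges": sum(1 for c in self.columns if c is PairClass.RNA_BULGE),
            "dna_bulges": sum(1 for c in self.columns if c is PairClass.DNA_BULGE),
            "wobble_total": sum(self.wobble_flags),
            "tv_total": sum(1 for c in self.columns if c is PairClass.TV),
            "rr_total": sum(1 for c in self.columns if c is PairClass.RR),
            "yy_total": sum(1 for c in self.columns if c is PairClass.YY),
        }
        L = self.guide_length
        n["mismatches_17_20"] = positional_mismatches(
            self, (max(1, L - SEED_WIDTH + 1), L)
        )
        return n

    def render(self) -> str:
        """Two-line text rendering with a match bar."""
        bar = "".join(
            "|" if c is PairClass.MATCH else (" " if c in (PairClass.RNA_BULGE, PairClass.DNA_BULGE) else ".")
            for c in self.columns
        )
        return f"guide {self.aligned_guide}\n      {bar}\nsite  {self.aligned_site}"


def positional_mismatches(alignment: GuideTargetAlignment, window: Tuple[int, int]) -> int:
    """Count mismatch columns whose guide position lies in [lo, hi] (1-based)."""
    lo, hi = window
    L = alignment.guide_length
    if lo < 1 or hi > L or lo > hi:
        raise ValueError(f"window {window} outside guide positions 1..{L}")
    return sum(
        1
        for c, p in zip(alignment.columns, alignment.guide_positions())
        if c in MISMATCH_CLASSES and p is not None and lo <= p <= hi
    )


def align_guide_to_site(
    guide: str, protospacer: str, scoring: Scoring = Scoring()
) -> GuideTargetAlignment:
    """Optimal global (Needleman-Wunsch) alignment of guide vs protospacer.

    Linear gap penalty; deterministic traceback preferring diagonal over
    gap-in-site (RNA bulge) over gap-in-guide (DNA bulge), so ties always
    resolve to a single alignment.
    """
    g = guide.upper().replace("U", "T")
    s = protospacer.upper()
    if not g or not s:
        raise ValueError("empty sequence")
    for seq, what in ((g, "guide"), (s, "protospacer")):
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(f"{what} contains non-ACGT symbols: {sorted(bad)}")

    n, m = len(g), len(s)
    mt, mm, gp = scoring.match, scoring.mismatch, scoring.gap
    # F[i][j] = best score aligning g[:i] with s[:j]
    F = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        F[i][0] = i * gp
    for j in range(1, m + 1):
        F[0][j] = j * gp
    for i in range(1, n + 1):
        gi = g[i - 1]
        for j in range(1, m + 1):
            diag = F[i - 1][j - 1] + (mt if gi == s[j - 1] else mm)
            up = F[i - 1][j] + gp
            left = F[i][j - 1] + gp
            F[i][j] = max(diag, up, left)

    # traceback, diag > up (gap in site) > left (gap in guide)
    ag, as_ = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and F[i][j] == F[i - 1][j - 1] + (mt if g[i - 1] == s[j - 1] else mm):
            ag.append(g[i - 1])
            as_.append(s[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and F[i][j] == F[i - 1][j] + gp:
            ag.append(g[i - 1])
            as_.append(GAP)
            i -= 1
        else:
            ag.append(GAP)
            as_.append(s[j - 1])
            j -= 1
    return GuideTargetAlignment(
        aligned_guide="".join(reversed(ag)),
        aligned_site="".join(reversed(as_)),
        score=F[n][m],
        scoring=scoring,
    )
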