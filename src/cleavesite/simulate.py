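"""Synthetic guide/site dataset generator.

The curated plant dataset behind this pipeline (51 sgRNAs with 174
on-target and 205 off-target sites across 15 crops) is not publicly
distributable, so this module generates labeled datasets with the same
per-crop counts and the statistical structure CRISPR off-target data is
known for: on-targets are exact protospacer matches with an NGG PAM;
off-targets carry 1-6 substitutions whose positions are biased away
from the PAM-proximal seed region (mismatches there tend to abolish
cleavage, so observed off-targets are depleted in seed mismatches),
occasionally a 1-nt bulge, and an NAG PAM in a minority of cases.

Every draw descends from a single seed, so datasets are byte-identical
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .records import GuideRecord, LabeledDataset, TargetSiteRecord

_NT = np.array(list("ACGT"))

#: Per-crop (name, n_guides, n_on_targets, n_off_targets) of the curated
#: plant corpus this generator emulates (51 guides, 174 on-targets and
#: 205 off-targets, 379 sites in total). The published per-crop table is
#: internally inconsistent: its on-target column sums to 184 against a
#: printed total of 174 on which every downstream count (379 data
#: points, the 265/114 split) relies. The maize on-target count is taken
#: as 21 (a single-digit slip from 31 reconciles the column with its
#: total); all other rows are as published.
CROP_PROFILE = (
    ("Rice", 8, 40, 36),
    ("Wheat", 5, 19, 30),
    ("Soybean", 2, 10, 5),
    ("Cotton", 8, 20, 33),
    ("Cucumber", 2, 2, 5),
    ("Tobacco", 2, 6, 5),
    ("Strawberry", 2, 5, 7),
    ("Watermelon", 2, 2, 2),
    ("Tomato", 4, 10, 13),
    ("Grape", 2, 8, 10),
    ("Potato", 2, 5, 3),
    ("Apple", 1, 6, 4),
    ("Orange", 4, 15, 20),
    ("Maize", 6, 21, 23),
    ("Barley", 1, 5, 9),
)


@dataclass
class CropCounts:
    name: str
    n_guides: int
    n_on_targets: int
    n_off_targets: int


@dataclass
class GenerationProfile:
    """All knobs of the generator; defaults are the emulated study conditions.

    ``off_target_mismatch_distribution`` is a probability mass over
    mismatch counts 1..6 (0 mismatches never occurs for label-0 sites);
    ``pam_proximal_mismatch_bias`` b >= 1 down-weights each seed-region
    position (17-20) by 1/b when placing mismatches;
    ``nag_pam_probability_off_target`` is the fraction of off-targets
    carrying an NAG instead of NGG PAM.
    """

    crops: list = field(
        default_factory=lambda: [CropCounts(*row) for row in CROP_PROFILE]
    )
    guide_length_range: tuple = (17, 20)
    context_length: int = 223
    off_target_mismatch_distribution: dict = field(
        default_factory=lambda: {1: 0.15, 2: 0.25, 3: 0.25, 4: 0.20, 5: 0.10, 6: 0.05}
    )
    pam_proximal_mismatch_bias: float = 4.0
    bulge_probability: float = 0.1
    nag_pam_probability_off_target: float = 0.2
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.guide_length_range
        if not (17 <= lo <= hi <= 20):
            raise ValueError(f"guide_length_range {self.guide_length_range} outside [17, 20]")
        dist = self.off_target_mismatch_distribution
        if min(dist) < 1 or not np.isclose(sum(dist.values()), 1.0):
            raise ValueError("mismatch distribution must be a pmf with support starting at 1")
        if self.pam_proximal_mismatch_bias < 1:
            raise ValueError("pam_proximal_mismatch_bias must be >= 1")
        for p in (self.bulge_probability, self.nag_pam_probability_off_target):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.context_length < 223:
            raise ValueError("context_length must be >= 223")

    @property
    def totals(self) -> dict:
        return {
            "guides": sum(c.n_guides for c in self.crops),
            "on_targets": sum(c.n_on_targets for c in self.crops),
            "off_targets": sum(c.n_off_targets for c in self.crops),
        }

    def to_manifest(self) -> dict:
        return asdict(self)


def default_profile(seed: int = 0) -> GenerationProfile:
    return GenerationProfile(seed=seed)


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(_NT, size=length))


def generate_guide(rng, length: int, guide_id: str = "g1", crop: str = "") -> GuideRecord:
    """Uniform-random ACGT guide of the given length."""
    if not 17 <= length <= 20:
        raise ValueError(f"guide length {length} outside [17, 20]")
    return GuideRecord(guide_id=guide_id, sequence=_random_seq(rng, length), crop=crop)


def _embed(protospacer: str, pam: str, rng, context_length: int) -> tuple:
    """Random flanking context of total length context_length; returns (context, start)."""
    core = protospacer + pam
    spare = context_length - len(core)
    up = spare // 2
    down = spare - up
    context = _random_seq(rng, up) + core + _random_seq(rng, down)
    return context, up


def embed_on_target(
    guide: GuideRecord, rng, profile: GenerationProfile, site_id: str = "s1"
) -> TargetSiteRecord:
    """Label-1 site: exact protospacer match, NGG PAM, random context."""
    pam = str(rng.choice(_NT)) + "GG"
    context, start = _embed(guide.sequence, pam, rng, profile.context_length)
    return TargetSiteRecord(
        site_id=site_id,
        guide_id=guide.guide_id,
        protospacer=guide.sequence,
        pam=pam,
        context=context,
        label=1,
        protospacer_start=start,
        source="synthetic:on_target",
    )


def _seed_weights(length: int, bias: float) -> np.ndarray:
    """Per-position mismatch placement weights; seed region down-weighted by 1/bias."""
    w = np.ones(length)
    w[max(0, length - 4):] = 1.0 / bias
    return w / w.sum()


def _draw_protospacer(guide: GuideRecord, rng, profile: GenerationProfile) -> tuple:
    dist = profile.off_target_mismatch_distribution
    ks = sorted(dist)
    k = int(rng.choice(ks, p=[dist[x] for x in ks]))
    seq = list(guide.sequence)
    weights = _seed_weights(len(seq), profile.pam_proximal_mismatch_bias)
    positions = rng.choice(len(seq), size=k, replace=False, p=weights)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = str(rng.choice(alternatives))
    events = [f"sub@{p + 1}" for p in sorted(positions)]
    bulged = rng.random() < profile.bulge_probability
    if bulged:
        pos = int(rng.integers(0, len(seq)))
        if rng.random() < 0.5:
            del seq[pos]  # site one base short: RNA bulge
            events.append(f"del@{pos + 1}")
        else:
            seq.insert(pos, str(rng.choice(_NT)))  # extra site base: DNA bulge
            events.append(f"ins@{pos + 1}")
    return seq, events, bulged


def mutate_off_target(
    guide: GuideRecord, rng, profile: GenerationProfile, site_id: str = "s1"
) -> TargetSiteRecord:
    """Label-0 site: k substitutions (k >= 1), optional 1-nt bulge, NGG or NAG PAM."""
    from .alignment import align_guide_to_site
    from .features import MAX_BULGES

    # a 1-nt indel next to clustered substitutions can re-register under
    # optimal alignment as several gaps; redraw so every emitted site
    # stays within the featurization bulge cap
    for _ in range(100):
        seq, events, bulged = _draw_protospacer(guide, rng, profile)
        if not bulged:
            break
        counts = align_guide_to_site(guide.sequence, "".join(seq)).counts
        if counts["rna_bulges"] + counts["dna_bulges"] <= MAX_BULGES:
            break
    pam_mid = "AG" if rng.random() < profile.nag_pam_probability_off_target else "GG"
    pam = str(rng.choice(_NT)) + pam_mid
    protospacer = "".join(seq)
    context, start = _embed(protospacer, pam, rng, profile.context_length)
    return TargetSiteRecord(
        site_id=site_id,
        guide_id=guide.guide_id,
        protospacer=protospacer,
        pam=pam,
        context=context,
        label=0,
        protospacer_start=start,
        source="synthetic:off_target:" + ",".join(events),
    )


def generate_dataset(
    profile: Optional[GenerationProfile] = None, seed: Optional[int] = None
) -> LabeledDataset:
    """Generate a full labeled dataset with the profile's exact per-crop counts."""
    profile = profile or default_profile()
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    lo, hi = profile.guide_length_range
    guides, sites = [], []
    g_i, s_i = 0, 0
    for crop in profile.crops:
        crop_guides = []
        for _ in range(crop.n_guides):
            g_i += 1
            length = int(rng.integers(lo, hi + 1))
            crop_guides.append(generate_guide(rng, length, f"g{g_i:03d}", crop.name))
        guides.extend(crop_guides)
        # sites distributed round-robin across the crop's guides
        for j in range(crop.n_on_targets):
            s_i += 1
            sites.append(
                embed_on_target(crop_guides[j % len(crop_guides)], rng, profile, f"s{s_i:04d}")
            )
        for j in range(crop.n_off_targets):
            s_i += 1
            sites.append(
                mutate_off_target(crop_guides[j % len(crop_guides)], rng, profile, f"s{s_i:04d}")
            )
    return LabeledDataset(guides=guides, sites=sites)
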