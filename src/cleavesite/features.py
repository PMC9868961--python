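"""The 30-feature registry: alignment, nucleotide-content, and PAM features.

Each guide/site pair is summarized by thirty named features in three
blocks:

* alignment block (9): pairwise alignment score, mismatch and bulge
  counts, mismatch typing (wobble / transversion / purine-purine /
  pyrimidine-pyrimidine), seed-region (positions 17-20) mismatches;
* nucleotide-content block (12): identities at guide positions 2, 4,
  4-5 and 20, GC content and nearest-neighbor DNA enthalpy over the
  extended 223-nt context window, plus genomic-context annotations
  (minor groove width at the PAM, DNase hypersensitivity, guanine
  occupancy, nucleosome distance, transcription/coding flags);
* PAM block (9): PAM type (NGG/NAG/other), the PAM N nucleotide, the
  three downstream bases at +1/+2/+5, exon membership and strand
  expression annotations.

Categorical features are one-hot encoded in a fixed registry order, so
the expanded matrix header is identical across runs; fields that can be
missing (downstream bases past a short context) expand to an all-zero
one-hot group plus a missingness flag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

from .alignment import GuideTargetAlignment, Scoring, align_guide_to_site
from .annotations import AnnotationBundle
from .records import CONTEXT_LEN, GuideRecord, TargetSiteRecord

_NT = ("A", "C", "G", "T")
_DINT = tuple(a + b for a in _NT for b in _NT)
_PAM_TYPES = ("NGG", "NAG", "OTHER")

#: Maximum bulges tolerated at featurization; larger indel structures are
#: outside the CRISPR off-target regime.
MAX_BULGES = 2


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    block: str
    kind: str  # "numeric" | "categorical"
    levels: tuple = ()
    can_be_missing: bool = False

    def columns(self) -> list:
        if self.kind == "numeric":
            return [self.name]
        cols = [f"{self.name}={lv}" for lv in self.levels]
        if self.can_be_missing:
            cols.append(f"{self.name}_missing")
        return cols


FEATURE_REGISTRY = (
    # alignment block
    FeatureSpec("alignment_score", "alignment", "numeric"),
    FeatureSpec("wobble_total", "alignment", "numeric"),
    FeatureSpec("rna_bulges", "alignment", "numeric"),
    FeatureSpec("mismatches_17_20", "alignment", "numeric"),
    FeatureSpec("mismatches", "alignment", "numeric"),
    FeatureSpec("dna_bulges", "alignment", "numeric"),
    FeatureSpec("tv_total", "alignment", "numeric"),
    FeatureSpec("rr_total", "alignment", "numeric"),
    FeatureSpec("yy_total", "alignment", "numeric"),
    # nucleotide-content block
    FeatureSpec("nt_position_20", "content", "categorical", _NT),
    FeatureSpec("mgw_pam", "content", "numeric"),
    FeatureSpec("dna_enthalpy_223", "content", "numeric"),
    FeatureSpec("nt_position_2", "content", "categorical", _NT),
    FeatureSpec("dhs_signal", "content", "numeric"),
    FeatureSpec("guanine_occupancy", "content", "numeric"),
    FeatureSpec("distance_from_nucleosome", "content", "numeric"),
    FeatureSpec("nt_positions_4_5", "content", "categorical", _DINT),
    FeatureSpec("transcription_region", "content", "numeric"),
    FeatureSpec("coding_region", "content", "numeric"),
    FeatureSpec("gc_content_extended", "content", "numeric"),
    FeatureSpec("nt_position_4", "content", "categorical", _NT),
    # PAM block
    FeatureSpec("pam_type", "pam", "categorical", _PAM_TYPES),
    FeatureSpec("in_exon_non_ngg", "pam", "numeric"),
    FeatureSpec("downstream_nt_1", "pam", "categorical", _NT, can_be_missing=True),
    FeatureSpec("downstream_nt_5", "pam", "categorical", _NT, can_be_missing=True),
    FeatureSpec("downstream_nt_2", "pam", "categorical", _NT, can_be_missing=True),
    FeatureSpec("in_exon_ngg", "pam", "numeric"),
    FeatureSpec("ngg_strand_expression", "pam", "numeric"),
    FeatureSpec("non_ngg_strand_expression", "pam", "numeric"),
    FeatureSpec("pam_n", "pam", "categorical", _NT),
)

#: Auxiliary flag: 1 when the extended GC/enthalpy window was shorter than
#: the full 223 nt.
CONTEXT_TRUNCATED_FLAG = "context_truncated"


def feature_columns() -> list:
    """Expanded matrix header, in stable registry order."""
    cols = []
    for spec in FEATURE_REGISTRY:
        cols.extend(spec.columns())
    cols.append(CONTEXT_TRUNCATED_FLAG)
    return cols


def registry_manifest() -> list:
    """Machine-readable registry description (name, block, type, encoding)."""
    return [
        {
            "name": s.name,
            "block": s.block,
            "type": s.kind,
            "levels": list(s.levels),
            "can_be_missing": s.can_be_missing,
            "columns": s.columns(),
        }
        for s in FEATURE_REGISTRY
    ]


def _load_default_enthalpy() -> dict:
    with resources.files("cleavesite.data").joinpath(
        "nn_enthalpy_santalucia1998.json"
    ).open() as fh:
        return json.load(fh)["delta_h"]


_DEFAULT_DH = None


def nn_enthalpy(seq: str, table: Optional[dict] = None) -> float:
    """Nearest-neighbor duplex enthalpy (kcal/mol): sum over dinucleotide stacks.

    Windows containing N are handled by summing over the maximal N-free
    runs (the window is truncated at each N), with a warning.
    """
    global _DEFAULT_DH
    if table is None:
        if _DEFAULT_DH is None:
            _DEFAULT_DH = _load_default_enthalpy()
        table = _DEFAULT_DH
    seq = seq.upper()
    if len(seq) < 2:
        warnings.warn("nn_enthalpy: sequence shorter than one dinucleotide step; returning 0")
        return 0.0
    if "N" in seq:
        warnings.warn("nn_enthalpy: window contains N; truncating at ambiguous bases")
        return sum(nn_enthalpy(run, table) for run in seq.split("N") if len(run) >= 2)
    total = 0.0
    for i in range(len(seq) - 1):
        step = seq[i : i + 2]
        if step not in table:
            raise KeyError(f"unknown dinucleotide step {step!r}")
        total += table[step]
    return total


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N bases are excluded from both counts."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    denom = sum(seq.count(b) for b in _NT)
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / denom


@dataclass(frozen=True)
class PamFeatures:
    pam_type: str
    pam_n: str
    downstream_nt_1: Optional[str] = None
    downstream_nt_2: Optional[str] = None
    downstream_nt_5: Optional[str] = None


def pam_features(context: str, protospacer_end_offset: int) -> PamFeatures:
    """PAM type and downstream bases read from the context window.

    ``protospacer_end_offset`` is the 0-based offset of the first PAM
    base. PAM type is decided by PAM positions 2-3 alone (NGG / NAG /
    OTHER). Downstream bases 1, 2 and 5 are read 3' of the PAM and
    flagged missing (None) when the context ends first.
    """
    context = context.upper()
    pam = context[protospacer_end_offset : protospacer_end_offset + 3]
    if len(pam) < 3:
        raise ValueError("context too short to contain the PAM")
    if pam[1:] == "GG":
        ptype = "NGG"
    elif pam[1:] == "AG":
        ptype = "NAG"
    else:
        ptype = "OTHER"

    def _downstream(k: int) -> Optional[str]:
        idx = protospacer_end_offset + 3 + (k - 1)
        if idx < len(context) and context[idx] in _NT:
            return context[idx]
        return None

    return PamFeatures(
        pam_type=ptype,
        pam_n=pam[0],
        downstream_nt_1=_downstream(1),
        downstream_nt_2=_downstream(2),
        downstream_nt_5=_downstream(5),
    )


def positional_nucleotides(protospacer: str) -> dict:
    """Bases at guide positions 2, 4, 4-5 and 20 (1 = PAM-distal).

    For protospacers shorter than 20 nt, "position 20" means the
    PAM-proximal (last) base.
    """
    seq = protospacer.upper()
    if len(seq) < 5:
        raise ValueError(f"protospacer too short ({len(seq)} nt) for positional features")
    return {
        "nt_position_2": seq[1],
        "nt_position_4": seq[3],
        "nt_positions_4_5": seq[3:5],
        "nt_position_20": seq[19] if len(seq) >= 20 else seq[-1],
    }


def extended_window(site: TargetSiteRecord, length: int = CONTEXT_LEN) -> str:
    """The extended-context window for GC/enthalpy, centered on the protospacer.

    Uses the site's context, trimmed symmetrically-as-possible around the
    protospacer+PAM to ``length`` nt; shorter contexts are returned whole.
    """
    ctx = site.context
    if len(ctx) <= length:
        return ctx
    core_lo = site.protospacer_start
    core_hi = site.protospacer_end + 3
    spare = max(0, length - (core_hi - core_lo))
    lo = core_lo - spare // 2
    hi = core_hi + (spare - spare // 2)
    if lo < 0:
        hi, lo = hi - lo, 0
    if hi > len(ctx):
        lo, hi = max(0, lo - (hi - len(ctx))), len(ctx)
    return ctx[lo:hi]


def build_feature_vector(
    guide: GuideRecord,
    site: TargetSiteRecord,
    alignment: Optional[GuideTargetAlignment] = None,
    annotations: Optional[AnnotationBundle] = None,
    scoring: Scoring = Scoring(),
    max_bulges: int = MAX_BULGES,
) -> pd.Series:
    """Assemble the expanded feature vector for one guide/site pair.

    A pure function of its inputs: identical inputs yield identical
    vectors. The alignment is computed when not supplied.
    """
    if site.guide_id != guide.guide_id:
        raise ValueError(
            f"site {site.site_id!r} links guide {site.guide_id!r}, got {guide.guide_id!r}"
        )
    if alignment is None:
        alignment = align_guide_to_site(guide.sequence, site.protospacer, scoring)
    counts = alignment.counts
    if counts["rna_bulges"] + counts["dna_bulges"] > max_bulges:
        raise ValueError(
            f"site {site.site_id!r}: {counts['rna_bulges'] + counts['dna_bulges']} bulges "
            f"exceed the configured maximum of {max_bulges}"
        )
    if annotations is None:
        annotations = AnnotationBundle()

    window = extended_window(site)
    pam = pam_features(site.context, site.protospacer_end)
    posnt = positional_nucleotides(site.protospacer)

    values = {
        "alignment_score": alignment.score,
        "wobble_total": counts["wobble_total"],
        "rna_bulges": counts["rna_bulges"],
        "mismatches_17_20": counts["mismatches_17_20"],
        "mismatches": counts["mismatches"],
        "dna_bulges": counts["dna_bulges"],
        "tv_total": counts["tv_total"],
        "rr_total": counts["rr_total"],
        "yy_total": counts["yy_total"],
        "mgw_pam": annotations.mgw_pam,
        "dna_enthalpy_223": nn_enthalpy(window),
        "dhs_signal": annotations.dhs_signal,
        "guanine_occupancy": annotations.guanine_occupancy,
        "distance_from_nucleosome": annotations.distance_from_nucleosome,
        "transcription_region": annotations.transcription_region,
        "coding_region": annotations.coding_region,
        "gc_content_extended": gc_content(window),
        "in_exon_non_ngg": annotations.in_exon_non_ngg,
        "in_exon_ngg": annotations.in_exon_ngg,
        "ngg_strand_expression": annotations.ngg_strand_expression,
        "non_ngg_strand_expression": annotations.non_ngg_strand_expression,
        **posnt,
        "pam_type": pam.pam_type,
        "pam_n": pam.pam_n,
        "downstream_nt_1": pam.downstream_nt_1,
        "downstream_nt_2": pam.downstream_nt_2,
        "downstream_nt_5": pam.downstream_nt_5,
    }

    row = {}
    for spec in FEATURE_REGISTRY:
        v = values[spec.name]
        if spec.kind == "numeric":
            row[spec.name] = float(v)
        else:
            for lv in spec.levels:
                row[f"{spec.name}={lv}"] = 1.0 if v == lv else 0.0
            if spec.can_be_missing:
                row[f"{spec.name}_missing"] = 1.0 if v is None else 0.0
            elif v not in spec.levels:
                raise ValueError(f"{spec.name}: unexpected level {v!r}")
    row[CONTEXT_TRUNCATED_FLAG] = 0.0 if len(window) >= CONTEXT_LEN else 1.0
    return pd.Series(row, index=feature_columns())


def featurize_dataset(ds, provider=None, scoring: Scoring = Scoring()) -> pd.DataFrame:
    """Compute the feature matrix for every site; also stored on the dataset."""
    from .annotations import NeutralAnnotationProvider

    provider = provider or NeutralAnnotationProvider()
    guides = {g.guide_id: g for g in ds.guides}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # N-padding warnings are per-site noise here
        rows = [
            build_feature_vector(
                guides[s.guide_id], s, annotations=provider.annotate(s), scoring=scoring
            )
            for s in ds.sites
        ]
    mat = pd.DataFrame(rows, index=ds.site_ids)
    mat.index.name = "site_id"
    ds.features = mat
    return mat
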