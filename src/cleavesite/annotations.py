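"""Genomic-context annotation features via a pluggable provider interface.

Several features of the registry (chromatin accessibility, nucleosome
distance, strand-specific expression, exon/transcription/coding flags,
guanine occupancy, minor groove width at the PAM) describe the genomic
neighbourhood of a site and require genome-browser tracks that the
pipeline deliberately does not download. A provider returns one
:class:`AnnotationBundle` per site; the default provider returns a
documented neutral value for every field so the pipeline is runnable
on sequence alone, and a file-backed provider serves user-supplied
per-site tracks from a tab-delimited table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import pandas as pd

_BINARY_FIELDS = ("in_exon_ngg", "in_exon_non_ngg", "transcription_region", "coding_region")


@dataclass(frozen=True)
class AnnotationBundle:
    """Per-site genomic-context values; every field has a neutral default.

    ``mgw_pam`` is the DNA minor groove width (Angstrom) at the NNGGN
    pentamer spanning the PAM; 0.0 denotes "unknown" rather than a
    physical width.
    """

    dhs_signal: float = 0.0
    distance_from_nucleosome: float = 0.0
    guanine_occupancy: float = 0.0
    mgw_pam: float = 0.0
    in_exon_ngg: int = 0
    in_exon_non_ngg: int = 0
    transcription_region: int = 0
    coding_region: int = 0
    ngg_strand_expression: float = 0.0
    non_ngg_strand_expression: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in _BINARY_FIELDS:
                if v not in (0, 1):
                    raise ValueError(f"{f.name} must be 0 or 1, got {v!r}")
            elif not math.isfinite(float(v)):
                raise ValueError(f"{f.name} must be finite, got {v!r}")


ANNOTATION_FIELDS = tuple(f.name for f in fields(AnnotationBundle))


class NeutralAnnotationProvider:
    """Returns the neutral default bundle for every site."""

    def annotate(self, site) -> AnnotationBundle:
        return AnnotationBundle()


class TableAnnotationProvider:
    """Serves annotations from a tab-delimited track table.

    The table must have a ``site_id`` column; any subset of the
    :class:`AnnotationBundle` field names may follow. Sites absent from
    the table (or absent columns) fall back to neutral defaults.
    """

    def __init__(self, path):
        df = pd.read_csv(path, sep="\t")
        if "site_id" not in df.columns:
            raise ValueError(f"{path}: annotation table needs a site_id column")
        unknown = set(df.columns) - {"site_id", *ANNOTATION_FIELDS}
        if unknown:
            raise ValueError(f"{path}: unknown annotation columns {sorted(unknown)}")
        self._rows = {
            r["site_id"]: {k: r[k] for k in df.columns if k != "site_id" and pd.notna(r[k])}
            for r in df.to_dict("records")
        }

    def annotate(self, site) -> AnnotationBundle:
        values = self._rows.get(site.site_id, {})
        ints = {k: int(v) for k, v in values.items() if k in _BINARY_FIELDS}
        floats = {k: float(v) for k, v in values.items() if k not in _BINARY_FIELDS}
        return AnnotationBundle(**ints, **floats)
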