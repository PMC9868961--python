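"""Readers and writers: guide FASTA, site tables, feature matrices.

Guides travel as FASTA (one record per guide_id, crop tag in the
description); sites as a delimited table with a documented header. The
feature matrix is CSV with columns in registry order plus a trailing
``label`` column.
"""

from __future__ import annotations

import os
from typing import Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import GuideRecord, LabeledDataset, TargetSiteRecord, ValidationError

SITE_COLUMNS = [
    "site_id",
    "guide_id",
    "protospacer",
    "pam",
    "context",
    "label",
    "protospacer_start",
    "strand",
    "source",
]
_REQUIRED_SITE_COLUMNS = SITE_COLUMNS[:6]


class DatasetFormatError(ValueError):
    """Input files are structurally invalid; message carries row diagnostics."""


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_guides(fasta_path) -> list:
    guides = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        crop = rec.description[len(rec.id):].strip() if rec.description else ""
        guides.append(GuideRecord(guide_id=rec.id, sequence=str(rec.seq), crop=crop))
    return guides


def write_guides(guides, fasta_path) -> None:
    recs = [
        SeqRecord(Seq(g.sequence), id=g.guide_id, description=g.crop)
        for g in guides
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")


def read_dataset(guides_fasta, sites_table) -> LabeledDataset:
    """Read and validate a labeled dataset; reject bad rows with diagnostics."""
    for p in (guides_fasta, sites_table):
        if not os.path.exists(str(p)):
            raise FileNotFoundError(str(p))
    guides = read_guides(guides_fasta)
    df = pd.read_csv(sites_table, sep=_sep_for(sites_table), dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_SITE_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"site table {sites_table}: missing columns {missing}")

    known_guides = {g.guide_id for g in guides}
    sites, problems = [], []
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based, after header
        try:
            if row["guide_id"] not in known_guides:
                raise ValidationError(f"unknown guide_id {row['guide_id']!r}")
            label_raw = row["label"]
            if label_raw not in ("0", "1"):
                raise ValidationError(f"label {label_raw!r} not in {{0, 1}}")
            sites.append(
                TargetSiteRecord(
                    site_id=row["site_id"],
                    guide_id=row["guide_id"],
                    protospacer=row["protospacer"],
                    pam=row["pam"],
                    context=row["context"],
                    label=int(label_raw),
                    protospacer_start=int(row.get("protospacer_start", 0) or 0),
                    strand=row.get("strand", "+") or "+",
                    source=row.get("source", "") or "",
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {rowno} (site_id={row.get('site_id', '?')!r}): {exc}")
    if problems:
        raise DatasetFormatError(
            f"site table {sites_table}: {len(problems)} invalid row(s):\n  " + "\n  ".join(problems)
        )
    return LabeledDataset(guides=guides, sites=sites)


def write_dataset(ds: LabeledDataset, guides_fasta, sites_table) -> None:
    write_guides(ds.guides, guides_fasta)
    rows = [
        {
            "site_id": s.site_id,
            "guide_id": s.guide_id,
            "protospacer": s.protospacer,
            "pam": s.pam,
            "context": s.context,
            "label": s.label,
            "protospacer_start": s.protospacer_start,
            "strand": s.strand,
            "source": s.source,
        }
        for s in ds.sites
    ]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(
        sites_table, sep=_sep_for(sites_table), index=False
    )


def write_feature_matrix(ds: LabeledDataset, path, precision: int = 10) -> None:
    """Write the site feature matrix with a trailing label column.

    Numeric formatting round-trips losslessly at the stated precision.
    """
    if ds.features is None:
        raise ValueError("dataset has no computed features")
    if len(ds.sites) == 0:
        raise ValueError("refusing to write feature matrix for an empty dataset")
    out = ds.features.copy()
    out["label"] = ds.labels.values
    out.to_csv(path, index=True, index_label="site_id", float_format=f"%.{precision}g")


def read_feature_matrix(path) -> Tuple[pd.DataFrame, pd.Series]:
    """Return (features, labels) from a matrix written by write_feature_matrix."""
    df = pd.read_csv(path, index_col="site_id")
    if "label" not in df.columns:
        raise DatasetFormatError(f"{path}: no label column")
    labels = df.pop("label").astype(int)
    return df, labels
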