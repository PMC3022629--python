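"""Serialize association results as UCSC custom tracks and tab-delimited tables.

Track export uses the bedGraph dialect: each track is a
``track type=bedGraph name=... description=...`` header line followed by
``chrom<TAB>start<TAB>end<TAB>score`` rows.  Scores are -log10(p), capped
(default 50) so that near-perfect fits do not blow up the browser's y axis;
positions are converted from the 1-based MAP convention to UCSC's 0-based
half-open single-base intervals.  SNPs with NaN p are omitted from tracks
rather than plotted at 0, which would read as a fake null result.

The tab-delimited outputs follow the per-probe naming pattern
``pvalues<PROBE>.linear.assoc.txt`` (CHR SNP BP A1 N BETA SE STAT P),
``pvalues<PROBE>.linear.assoc.adjusted.txt`` (SNP RAW BONF HOLM SIDAK BH BY),
``<PROBE>.qassoc.means.txt`` (SNP CLASS N MEAN SD) and
``extracted_snps_with_expression_values<PROBE>.ped`` (the merged PED with
the expression value in the phenotype column).  Numbers print with 6
significant digits, p-values in scientific notation, missing as "NA".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .adjust import COLUMN_ORDER
from .assoc import GENOTYPE_CLASSES, AssociationResult
from .errors import OutputError
from .expression_io import MergedPhenotype
from .genotype_io import GenotypeDataset

DEFAULT_CAP = 50.0

_ADJ_HEADER = {"raw": "RAW", "bonferroni": "BONF", "holm": "HOLM",
               "sidak": "SIDAK", "bh": "BH", "by": "BY"}


def fmt(x, sci: bool = False) -> str:
    """Render one numeric field: 6 significant digits, 'NA' for missing."""
    if x is None:
        return "NA"
    if isinstance(x, float) and (math.isnan(x)):
        return "NA"
    if isinstance(x, float) and math.isinf(x):
        return "inf" if x > 0 else "-inf"
    if sci:
        return f"{x:.6e}"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{x:.6g}"


@dataclass
class Track:
    name: str
    description: str
    entries: list  # (chromosome, start, end, score)


@dataclass
class TrackSet:
    tracks: List[Track] = field(default_factory=list)


def score_from_p(p: float, cap: float = DEFAULT_CAP) -> float:
    """-log10(p), capped; p must be in (0, 1]."""
    return min(-math.log10(p), cap)


def make_tracks(
    probe_id: str,
    results: Sequence[AssociationResult],
    adjusted: Optional[pd.DataFrame] = None,
    methods: Sequence[str] = (),
    cap: float = DEFAULT_CAP,
) -> TrackSet:
    """Build one track per (probe x {raw} U selected adjustments).

    ``adjusted`` is the table from :func:`eqtlscan.adjust.adjust_all`,
    row-aligned with ``results``.  NaN-p SNPs are omitted.
    """
    ts = TrackSet()
    columns = ["raw"] + [m for m in COLUMN_ORDER[1:] if m in methods]
    for col in columns:
        if col == "raw":
            pvals = [r.p for r in results]
        else:
            if adjusted is None or col not in adjusted.columns:
                continue
            pvals = adjusted[col].tolist()
        entries = []
        for r, p in zip(results, pvals):
            if p is None or math.isnan(p):
                continue
            entries.append(
                (r.chromosome, r.position_bp - 1, r.position_bp, score_from_p(p, cap))
            )
        entries.sort(key=lambda e: (e[0], e[1]))
        ts.tracks.append(
            Track(
                name=f"{probe_id}_{col}",
                description=f"-log10 p ({col}) for probe {probe_id}",
                entries=entries,
            )
        )
    return ts


def write_custom_track(ts: TrackSet, sink) -> str:
    """Emit one bedGraph block per track; returns the text written."""
    lines = []
    for tr in ts.tracks:
        lines.append(
            f'track type=bedGraph name="{tr.name}" description="{tr.description}"'
        )
        for chrom, start, end, score in tr.entries:
            lines.append(f"chr{chrom}\t{start}\t{end}\t{fmt(score)}")
    text = "\n".join(lines) + "\n"
    _write_text(sink, text)
    return text


def _write_text(sink, text: str) -> None:
    if hasattr(sink, "write"):
        sink.write(text)
        return
    try:
        Path(sink).write_text(text)
    except OSError as exc:
        raise OutputError(f"cannot write {sink}: {exc}") from exc


def _check_overwrite(path: Path, overwrite: bool) -> None:
    if path.exists() and not overwrite:
        raise OutputError(f"{path} exists; pass overwrite=True to replace it")


def assoc_table_path(out_dir, probe_id: str) -> Path:
    return Path(out_dir) / f"pvalues{probe_id}.linear.assoc.txt"


def adjusted_table_path(out_dir, probe_id: str) -> Path:
    return Path(out_dir) / f"pvalues{probe_id}.linear.assoc.adjusted.txt"


def means_table_path(out_dir, probe_id: str) -> Path:
    return Path(out_dir) / f"{probe_id}.qassoc.means.txt"


def ped_with_phenotype_path(out_dir, probe_id: str) -> Path:
    return Path(out_dir) / f"extracted_snps_with_expression_values{probe_id}.ped"


def write_assoc_table(
    results: Sequence[AssociationResult], probe_id: str, out_dir, overwrite: bool = False
) -> Path:
    """CHR SNP BP A1 N BETA SE STAT P, one row per SNP; NA for degenerate rows."""
    path = assoc_table_path(out_dir, probe_id)
    _check_overwrite(path, overwrite)
    lines = ["CHR\tSNP\tBP\tA1\tN\tBETA\tSE\tSTAT\tP"]
    for r in results:
        lines.append(
            "\t".join(
                [
                    r.chromosome,
                    r.snp_id,
                    str(r.position_bp),
                    r.minor_allele or "NA",
                    str(r.n_used),
                    fmt(r.beta),
                    fmt(r.se),
                    fmt(r.statistic),
                    fmt(r.p, sci=True),
                ]
            )
        )
    _write_text(path, "\n".join(lines) + "\n")
    return path


def write_adjusted_table(
    results: Sequence[AssociationResult],
    adjusted: pd.DataFrame,
    probe_id: str,
    out_dir,
    overwrite: bool = False,
) -> Path:
    """SNP RAW BONF HOLM SIDAK BH BY (columns limited to those computed)."""
    path = adjusted_table_path(out_dir, probe_id)
    _check_overwrite(path, overwrite)
    cols = [c for c in COLUMN_ORDER if c in adjusted.columns]
    lines = ["\t".join(["SNP"] + [_ADJ_HEADER[c] for c in cols])]
    for i, r in enumerate(results):
        lines.append(
            "\t".join([r.snp_id] + [fmt(adjusted[c].iloc[i], sci=True) for c in cols])
        )
    _write_text(path, "\n".join(lines) + "\n")
    return path


def write_means_table(
    results: Sequence[AssociationResult], probe_id: str, out_dir, overwrite: bool = False
) -> Path:
    """SNP CLASS N MEAN SD; three rows (homMajor/het/homMinor) per SNP."""
    path = means_table_path(out_dir, probe_id)
    _check_overwrite(path, overwrite)
    lines = ["SNP\tCLASS\tN\tMEAN\tSD"]
    for r in results:
        for cls in GENOTYPE_CLASSES:
            lines.append(
                "\t".join(
                    [
                        r.snp_id,
                        cls,
                        str(r.class_counts.get(cls, 0)),
                        fmt(r.class_means.get(cls, float("nan"))),
                        fmt(r.class_sds.get(cls, float("nan"))),
                    ]
                )
            )
    _write_text(path, "\n".join(lines) + "\n")
    return path


def write_ped_with_phenotype(
    ds: GenotypeDataset,
    merged: MergedPhenotype,
    probe_id: str,
    out_dir,
    overwrite: bool = False,
) -> Path:
    """The merged PED with the expression value in the phenotype column."""
    path = ped_with_phenotype_path(out_dir, probe_id)
    _check_overwrite(path, overwrite)
    lines = []
    for i, s in enumerate(ds.samples):
        fields = [
            s.family_id,
            s.individual_id,
            s.paternal_id,
            s.maternal_id,
            str(s.sex),
            fmt(float(merged.phenotype[i])),
        ]
        fields.extend(ds.calls[i].ravel().tolist())
        lines.append("\t".join(fields))
    _write_text(path, "\n".join(lines) + "\n")
    return path


def write_log(metadata: Dict, events: Sequence[str], sink) -> str:
    """Chronological run log: config echo, then one line per event."""
    lines = ["# eqtlscan run log", "## configuration"]
    for k in sorted(metadata):
        lines.append(f"{k} = {metadata[k]}")
    lines.append("## events")
    lines.extend(events)
    text = "\n".join(lines) + "\n"
    _write_text(sink, text)
    return text
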