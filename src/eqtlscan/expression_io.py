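"""Probe-level expression tables and genotype/phenotype sample alignment.

The canonical table layout is a TSV with header
``ProbeID<TAB>GeneSymbol<TAB><IID1><TAB><IID2>...`` and one row per probe.
Values are already-normalized array intensities and are used as-is (no
log-transform).  A gene may be represented by several probes; each probe is
analyzed separately downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple, Union

import pandas as pd

from .errors import ParseError, SelectionError
from .genotype_io import GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class ExpressionProfile:
    """One probe's normalized expression value per individual."""

    probe_id: str
    gene_symbol: str
    values: dict  # individual_id -> float


@dataclass
class MergedPhenotype:
    """Expression values aligned index-for-index with a genotype dataset."""

    individual_ids: list
    phenotype: list  # floats, same length as individual_ids

    def __post_init__(self):
        if len(self.individual_ids) != len(self.phenotype):
            raise ValueError("individual_ids and phenotype lengths differ")
        if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in self.phenotype):
            raise ValueError("merged phenotype must have no missing entries")


def read_expression_table(source: Union[str, Path, object]) -> List[ExpressionProfile]:
    """Read an expression TSV into one :class:`ExpressionProfile` per row.

    Rejects duplicate probe IDs, empty tables and non-numeric cells
    (the error names the offending probe row and sample column).
    """
    try:
        df = pd.read_csv(source, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError("expression table is empty") from exc
    if df.shape[0] == 0:
        raise ParseError("expression table has a header but no probe rows")
    if df.shape[1] < 3:
        raise ParseError(
            "expression table needs at least 3 columns: "
            "ProbeID, GeneSymbol, then one column per individual"
        )
    probe_col, gene_col = df.columns[0], df.columns[1]
    iids = list(df.columns[2:])

    dup = df[probe_col][df[probe_col].duplicated()].tolist()
    if dup:
        raise ParseError(f"duplicate probe_id(s): {sorted(set(dup))}")

    profiles = []
    for _, row in df.iterrows():
        probe = row[probe_col]
        values = {}
        for iid in iids:
            cell = row[iid]
            try:
                v = float(cell)
            except (TypeError, ValueError):
                v = float("nan")
            if cell is None or (isinstance(v, float) and math.isnan(v)):
                raise ParseError(
                    f"probe {probe}, sample {iid}: non-numeric cell '{cell}'"
                )
            values[iid] = v
        profiles.append(
            ExpressionProfile(probe_id=probe, gene_symbol=row[gene_col], values=values)
        )
    logger.info("read %d probes x %d samples", len(profiles), len(iids))
    return profiles


def probes_for_gene(table: List[ExpressionProfile], gene_symbol: str) -> List[str]:
    """Probe IDs whose gene symbol matches case-insensitively, in table order."""
    key = gene_symbol.casefold()
    hits = [p.probe_id for p in table if p.gene_symbol.casefold() == key]
    if not hits:
        known = sorted({p.gene_symbol for p in table})
        raise SelectionError(
            f"gene '{gene_symbol}' not found in expression table "
            f"({len(known)} genes present)"
        )
    return hits


def merge_samples(
    ds: GenotypeDataset, profile: ExpressionProfile
) -> Tuple[GenotypeDataset, MergedPhenotype]:
    """Intersect genotyped and expression-profiled individuals.

    Keeps exactly the individuals present in both sources, preserving the
    genotype dataset's sample order, and logs how many were dropped from
    each side.  Raises :class:`SelectionError` on an empty intersection.
    """
    expr_ids = set(profile.values)
    keep = [i for i, s in enumerate(ds.samples) if s.individual_id in expr_ids]
    if not keep:
        raise SelectionError(
            f"no overlap between genotyped samples (n={ds.n_samples}) and "
            f"expression samples (n={len(expr_ids)}) for probe {profile.probe_id}"
        )
    dropped_geno = ds.n_samples - len(keep)
    dropped_expr = len(expr_ids) - len(keep)
    if dropped_geno or dropped_expr:
        logger.info(
            "merge for probe %s: kept %d; dropped %d genotyped-only, %d expression-only",
            profile.probe_id, len(keep), dropped_geno, dropped_expr,
        )
    merged_ds = ds.subset_samples(keep)
    ids = merged_ds.sample_ids
    return merged_ds, MergedPhenotype(
        individual_ids=ids, phenotype=[profile.values[i] for i in ids]
    )
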