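"""Readers and writers for the genomic text formats the pipeline consumes.

Coordinate conventions
----------------------
* Segmentation and blacklist files are BED-like: 0-based, half-open.
* FIMO occurrence tables and mutation tables are 1-based, inclusive.
* All conversions happen at read/assignment time; every internal interval is
  0-based half-open, so a 1-based position ``q`` lies in region ``[start, end)``
  iff ``start < q <= end``.

Containers are plain :class:`pandas.DataFrame` objects with documented column
schemas; record-level dataclasses would add nothing for tables of this size.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "donor_id", "tumor_type"]

#: columns required in a FIMO-dialect TSV (``sequence_name`` is the chromosome)
FIMO_REQUIRED = ["motif_id", "sequence_name", "start", "stop", "strand", "score", "p-value"]


# ---------------------------------------------------------------------------
# segmentation / blacklist (BED-like)
# ---------------------------------------------------------------------------

def read_segmentation(path) -> pd.DataFrame:
    """Read a ChromHMM-style segmentation BED file.

    Expects >= 4 tab-separated columns: chrom, start, end, state.  Returns a
    frame with columns ``region_id, chrom, start, end, state, length_bp`` where
    ``region_id`` is a stable 0-based line index and coordinates are 0-based
    half-open as in the file.

    Raises
    ------
    ValueError
        On a malformed line (naming the 1-based line number) or a region with
        ``end <= start``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"segmentation line {lineno}: expected >=4 tab-separated "
                                 f"columns, got {len(parts)}")
            chrom, start_s, end_s, state = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"segmentation line {lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValueError(f"segmentation line {lineno}: end ({end}) <= start ({start})")
            rows.append((chrom, start, end, state))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    df.insert(0, "region_id", np.arange(len(df)))
    df["length_bp"] = df["end"] - df["start"]
    return df


def write_segmentation(regions: pd.DataFrame, path) -> None:
    regions[["chrom", "start", "end", "state"]].to_csv(path, sep="\t", header=False, index=False)


def read_blacklist(path) -> pd.DataFrame:
    """Read a blacklist BED (chrom, start, end; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    if (df["end"] <= df["start"]).any():
        raise ValueError("blacklist contains an interval with end <= start")
    return df


# ---------------------------------------------------------------------------
# FIMO occurrence tables
# ---------------------------------------------------------------------------

def read_fimo(path, p_value_cutoff: float = 1e-5) -> pd.DataFrame:
    """Read a FIMO TSV and keep occurrences with ``p-value <= p_value_cutoff``.

    Returns columns ``motif_id, chrom, start, stop, strand, score, p_value``
    with coordinates kept 1-based inclusive.  Strand is read but never used
    downstream.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lstrip("# ").strip() for c in df.columns]
    missing = [c for c in FIMO_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"FIMO file missing required columns: {missing}")
    df = df.rename(columns={"sequence_name": "chrom", "p-value": "p_value"})
    df = df[["motif_id", "chrom", "start", "stop", "strand", "score", "p_value"]]
    if ((df["p_value"] <= 0) | (df["p_value"] > 1)).any():
        raise ValueError("FIMO p-values must lie in (0, 1]")
    if (df["stop"] < df["start"]).any():
        raise ValueError("FIMO occurrence with stop < start")
    return df[df["p_value"] <= p_value_cutoff].reset_index(drop=True)


def write_fimo(occurrences: pd.DataFrame, path) -> None:
    out = occurrences.rename(columns={"chrom": "sequence_name", "p_value": "p-value"})
    out = out[["motif_id", "sequence_name", "start", "stop", "strand", "score", "p-value"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------

def read_mutations(path) -> pd.DataFrame:
    """Read a mutation TSV with header ``chrom,pos,ref,alt,donor_id,tumor_type``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str,
                                            "donor_id": str, "tumor_type": str})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation file missing required columns: {missing}")
    df = df[MUTATION_COLUMNS]
    if (df["pos"] < 1).any():
        raise ValueError("mutation with pos < 1")
    if (df["ref"] == df["alt"]).any():
        raise ValueError("mutation with ref == alt")
    return df


def write_mutations(mutations: pd.DataFrame, path) -> None:
    mutations[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_vcf_mutations(path, donor_id: str, tumor_type: str) -> pd.DataFrame:
    """Minimal VCF import: CHROM/POS/REF/ALT with donor identity supplied by
    the caller (e.g. from the filename).  Multi-allelic records are split."""
    from cyvcf2 import VCF

    rows = []
    for variant in VCF(str(path)):
        for alt in variant.ALT:
            rows.append((variant.CHROM, variant.POS, variant.REF, alt,
                         donor_id, tumor_type))
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


# ---------------------------------------------------------------------------
# interval assignment
# ---------------------------------------------------------------------------

def _locate(pos0: np.ndarray, starts: np.ndarray, ends: np.ndarray,
            ids: np.ndarray) -> np.ndarray:
    """Map 0-based positions onto sorted non-overlapping intervals.

    Returns the interval id for each position, -1 where the position falls in
    a gap.  ``starts`` must be sorted ascending.
    """
    idx = np.searchsorted(starts, pos0, side="right") - 1
    out = np.full(pos0.shape, -1, dtype=np.int64)
    valid = idx >= 0
    inside = np.zeros_like(valid)
    inside[valid] = pos0[valid] < ends[idx[valid]]
    out[inside] = ids[idx[inside]]
    return out


def locate_positions(chroms: pd.Series, pos0: pd.Series,
                     intervals: pd.DataFrame, id_column: str = "region_id") -> np.ndarray:
    """Vectorised per-chromosome interval lookup (0-based positions).

    ``intervals`` needs columns chrom/start/end plus ``id_column``; intervals
    are assumed non-overlapping within a chromosome.
    """
    chrom_arr = np.asarray(chroms)
    result = np.full(len(chrom_arr), -1, dtype=np.int64)
    pos0 = np.asarray(pos0, dtype=np.int64)
    by_chrom = {c: g.sort_values("start") for c, g in intervals.groupby("chrom")}
    for chrom in np.unique(chrom_arr):
        grp = by_chrom.get(chrom)
        if grp is None:
            continue
        loc = np.flatnonzero(chrom_arr == chrom)
        result[loc] = _locate(pos0[loc],
                              grp["start"].to_numpy(),
                              grp["end"].to_numpy(),
                              grp[id_column].to_numpy())
    return result


def assign_mutations(mutations: pd.DataFrame, regions: pd.DataFrame,
                     blacklist: pd.DataFrame | None = None):
    """Map mutations to segmentation regions, excluding blacklisted positions.

    A mutation at 1-based position ``q`` belongs to region ``[start, end)``
    iff ``start < q <= end``.  Blacklisted mutations are removed before any
    counting; mutations on chromosomes absent from the segmentation (or in
    segmentation gaps) are kept in the returned frame with ``region_id == -1``
    and tallied as unassigned — they do not contribute to the cohort total.

    Returns
    -------
    (assigned, counts, unassigned, total)
        ``assigned``: the non-blacklisted mutations with a ``region_id``
        column; ``counts``: per-region mutation counts indexed by region_id
        (every region present, zeros included); ``unassigned``: number of
        non-blacklisted mutations mapping to no region; ``total``: cohort
        total T = counts.sum().
    """
    mut = mutations.reset_index(drop=True).copy()
    pos0 = mut["pos"].to_numpy(dtype=np.int64) - 1
    if blacklist is not None and len(blacklist):
        bl = blacklist.copy()
        bl["iv_id"] = np.arange(len(bl))
        hit = locate_positions(mut["chrom"], pos0, bl, id_column="iv_id")
        mut = mut[hit < 0].reset_index(drop=True)
        pos0 = mut["pos"].to_numpy(dtype=np.int64) - 1
    region_id = locate_positions(mut["chrom"], pos0, regions)
    mut["region_id"] = region_id
    counts = (pd.Series(region_id[region_id >= 0])
              .value_counts()
              .reindex(regions["region_id"], fill_value=0)
              .rename("count"))
    unassigned = int((region_id < 0).sum())
    return mut, counts, unassigned, int(counts.sum())


# ---------------------------------------------------------------------------
# donor-level cohort filters
# ---------------------------------------------------------------------------

def filter_donors(donors: pd.DataFrame, min_donors: int = 5,
                  min_total: int = 30_000, iqr_factor: float = 1.5) -> list[str]:
    """Apply the cohort inclusion filters and return retained donor ids.

    ``donors`` needs columns ``donor_id, tumor_type, n_mutations,
    is_metastatic, assay``.  In order: metastatic donors are removed; when a
    donor carries both WGS and WES rows only WGS is kept; per-tumor-type IQR
    outliers (outside ``[Q1 - k*IQR, Q3 + k*IQR]``, quartiles by linear
    interpolation) are removed; tumor types with fewer than ``min_donors``
    retained donors or fewer than ``min_total`` total mutations are dropped.
    """
    df = donors.copy()
    df = df[~df["is_metastatic"].astype(bool)]
    # prefer WGS when a donor appears with both assays
    both = df.groupby("donor_id")["assay"].transform(lambda a: set(a) >= {"WGS", "WES"})
    df = df[~(both & (df["assay"] == "WES"))]

    retained: list[str] = []
    for tumor_type, grp in df.groupby("tumor_type"):
        if grp.empty:
            warnings.warn(f"tumor type {tumor_type!r}: empty group, skipped")
            continue
        counts = grp["n_mutations"].to_numpy(dtype=float)
        q1, q3 = np.percentile(counts, [25, 75])  # linear interpolation
        iqr = q3 - q1
        lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
        keep = grp[(counts >= lo) & (counts <= hi)]
        if len(keep) < min_donors:
            continue
        if keep["n_mutations"].sum() < min_total:
            continue
        retained.extend(keep["donor_id"].tolist())
    return retained
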