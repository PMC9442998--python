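"""On-disk interchange formats.

BED-style conventions on disk: 0-based half-open coordinates, tab-separated
bin and segment tables, CSV clinical/result tables, JSON for fits, QC and
the run manifest.  Human-readable reports use 1-based Mb labels
(``8:23.4-24`` style); see :func:`mb_label`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import SEGMENT_COLUMNS, SegmentProfile
from .genome import GenomeBins

BIN_COUNT_COLUMNS = ["chrom", "start", "end", "count"]


def mb_label(chrom: str, start: int, end: int) -> str:
    """Paper-style human-readable span label, 1-based Mb."""
    return f"{chrom}:{(start + 1) / 1e6:g}-{end / 1e6:g}"


# ---------------------------------------------------------------------------
# bin counts


def write_bin_counts(counts: np.ndarray, bins: GenomeBins, path) -> None:
    df = bins.key_frame()
    df["count"] = np.asarray(counts)
    df.to_csv(path, sep="\t", index=False)


def read_bin_counts(path, bins: GenomeBins) -> np.ndarray:
    """Read a per-bin count TSV keyed against the bin frame.

    Rows join on exact (chrom, start, end); row order is irrelevant.  Bins
    absent from the file come back as NaN (masked downstream, shrinking the
    burden denominator); rows not in the frame are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing_cols = set(BIN_COUNT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    key = bins.key_frame()
    key["chrom"] = key["chrom"].astype(str)
    merged = key.merge(df, on=["chrom", "start", "end"], how="left", indicator=False)
    if len(df) > 0:
        extra = df.merge(key.assign(_in=1), on=["chrom", "start", "end"], how="left")
        bad = extra["_in"].isna()
        if bad.any():
            first = extra.loc[bad].iloc[0]
            raise ValueError(f"{path}: row not in bin frame: "
                             f"{first['chrom']}:{first['start']}-{first['end']}")
    return merged["count"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# segment tables


def segments_to_frame(profiles: dict) -> pd.DataFrame:
    """Tidy cohort segment table from {sample_id: SegmentProfile}."""
    parts = []
    for sid, prof in profiles.items():
        sub = prof.segments.copy()
        sub.insert(0, "sample_id", sid)
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def write_segment_table(segments: pd.DataFrame, path) -> None:
    cols = ["sample_id", *SEGMENT_COLUMNS] if "sample_id" in segments.columns \
        else list(SEGMENT_COLUMNS)
    segments.to_csv(path, sep="\t", index=False, columns=cols)


_CALL_ALIASES = {"-1": -1, "0": 0, "1": 1, "+1": 1, "loss": -1, "neutral": 0,
                 "gain": 1, "del": -1, "amp": 1}


def read_segment_table(path, bins: GenomeBins, column_mapping: dict | None = None,
                       one_based: bool = False) -> dict:
    """Read a cohort segment TSV into {sample_id: SegmentProfile}.

    ``column_mapping`` maps required names (sample_id, chrom, start, end,
    call; optionally mean_log2) to the file's column names, so deposited
    segment tables with arbitrary headers can be ingested.  ``one_based``
    declares 1-based inclusive input coordinates, normalized to 0-based
    half-open internally.  Calls are normalized to {-1, 0, +1}; overlapping
    segments within a sample are rejected with their row numbers; unknown
    chromosomes are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = column_mapping or {}
    def col(name):
        src = mapping.get(name, name)
        if src not in df.columns:
            raise ValueError(f"{path}: cannot map column {name!r} (tried {src!r})")
        return df[src]

    out = pd.DataFrame({
        "sample_id": col("sample_id").astype(str),
        "chrom": col("chrom").astype(str).str.removeprefix("chr"),
        "start": col("start").astype(int),
        "end": col("end").astype(int),
        "call": col("call").astype(str).str.strip().str.lower().map(_CALL_ALIASES),
    })
    try:
        out["mean_log2"] = col("mean_log2").astype(float)
    except ValueError:
        out["mean_log2"] = np.nan
    if out["call"].isna().any():
        bad = out.index[out["call"].isna()][0]
        raise ValueError(f"{path}: unrecognized call value at row {bad + 2}")
    out["call"] = out["call"].astype(int)
    if one_based:
        out["start"] -= 1
    known = set(str(c) for c in bins.chroms)
    unknown = ~out["chrom"].isin(known)
    if unknown.any():
        raise ValueError(f"{path}: unknown chromosome "
                         f"{out.loc[unknown, 'chrom'].iloc[0]!r} at row "
                         f"{out.index[unknown][0] + 2}")
    profiles = {}
    for sid, sub in out.groupby("sample_id", sort=False):
        sub = sub.sort_values(["chrom", "start"],
                              key=lambda s: s.map(lambda v: _chrom_key(v, bins))
                              if s.name == "chrom" else s)
        for chrom, csub in sub.groupby("chrom"):
            starts = csub["start"].to_numpy()
            ends = csub["end"].to_numpy()
            overlap = np.flatnonzero(starts[1:] < ends[:-1])
            if overlap.size:
                i = csub.index[overlap[0]]
                j = csub.index[overlap[0] + 1]
                raise ValueError(f"{path}: overlapping segments for sample {sid} "
                                 f"at rows {i + 2} and {j + 2}")
        rows = []
        for row in sub.itertuples():
            lo, hi = bins.bin_span(row.chrom, row.start, row.end)
            rows.append({"chrom": row.chrom, "start": row.start, "end": row.end,
                         "first_bin": lo, "last_bin": hi - 1, "n_bins": hi - lo,
                         "mean_log2": row.mean_log2, "call": row.call})
        profiles[sid] = SegmentProfile(sample_id=str(sid),
                                       segments=pd.DataFrame(rows, columns=SEGMENT_COLUMNS))
    return profiles


def _chrom_key(chrom, bins: GenomeBins):
    order = {str(c): i for i, c in enumerate(bins.chroms)}
    return order.get(str(chrom), len(order))


# ---------------------------------------------------------------------------
# clinical tables


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False)


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str})


# ---------------------------------------------------------------------------
# manifest


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seed: int, outputs: dict, stages: dict) -> dict:
    """Run manifest: config snapshot, seed, per-output sha256, stage status."""
    manifest = {
        "seed": seed,
        "config": config,
        "stages": stages,
        "outputs": {name: {"path": str(p), "sha256": file_digest(p)}
                    for name, p in outputs.items() if Path(p).exists()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
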