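"""Decoding of multiplexed FISH localizations into chromosome traces.

Whole-chromosome imaging resolves each spot with a combined barcode: a
segment barcode identifying a 15-Mb segment and a spot barcode repeating
every ``repeat_period`` bp.  Each candidate fit carries one peak intensity
per segment frame; the segment is assigned by intensity z-score, and the
(segment, spot) pair decodes to a unique genomic coordinate.  When several
chromosome copies share a region of interest, ambiguous fits (more than one
high-quality fit at the same coordinate) are split by spectral clustering on
standardized spatial + genomic position, increasing the cluster count until
most coordinates (75th quantile) are unambiguous within their cluster;
remaining duplicates are resolved by the highest segment z-score.

Fit tables are pandas DataFrames with columns ``record_id, spot_barcode_id,
x_nm, y_nm, z_nm, fit_sd_nm, snr, region_id`` plus one ``intensity_seg<k>``
column per segment frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import SpectralClustering

logger = logging.getLogger(__name__)

__all__ = [
    "BarcodeScheme",
    "intensity_columns",
    "zscore_segment_assignment",
    "decode_coordinates",
    "spectral_disambiguation",
    "qc_filter",
]


@dataclass(frozen=True)
class BarcodeScheme:
    """Combinatorial barcode design: segment barcodes x repeating spot barcodes."""

    chromosome_length: int
    segment_size: int = 15_000_000
    spot_spacing: int = 1_000_000
    repeat_period: int = 30_000_000

    def __post_init__(self) -> None:
        if self.repeat_period % self.spot_spacing != 0:
            raise ValueError("repeat_period must be a multiple of spot_spacing")

    @property
    def n_segments(self) -> int:
        return -(-self.chromosome_length // self.segment_size)

    @property
    def n_spot_barcodes(self) -> int:
        return self.repeat_period // self.spot_spacing

    def coordinate(self, segment_id: int, spot_id: int) -> int | None:
        """Genomic coordinate of (segment, spot) or None if not decodable."""
        if not (0 <= segment_id < self.n_segments):
            return None
        if not (0 <= spot_id < self.n_spot_barcodes):
            return None
        seg_lo = segment_id * self.segment_size
        seg_hi = min(seg_lo + self.segment_size, self.chromosome_length)
        base = spot_id * self.spot_spacing
        hits = [base + m * self.repeat_period
                for m in range(self.chromosome_length // self.repeat_period + 1)
                if seg_lo <= base + m * self.repeat_period < seg_hi]
        return hits[0] if len(hits) == 1 else None

    def spot_id_of(self, coordinate: int) -> int:
        return (coordinate % self.repeat_period) // self.spot_spacing

    def segment_id_of(self, coordinate: int) -> int:
        return coordinate // self.segment_size


def intensity_columns(fits: pd.DataFrame) -> list[str]:
    cols = [c for c in fits.columns if c.startswith("intensity_seg")]
    if len(cols) < 2:
        raise ValueError("need at least 2 segment intensity columns")
    return sorted(cols, key=lambda c: int(c.removeprefix("intensity_seg")))


def zscore_segment_assignment(intensities: np.ndarray
                              ) -> tuple[int | None, float]:
    """Segment with the highest intensity z-score: z_k = (I_k - mean I) / sd I.

    Returns (None, nan) when the intensities carry no information (zero
    variance), flagging the fit as ambiguous.
    """
    x = np.asarray(intensities, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 candidate segment intensities")
    sd = x.std(ddof=0)
    if sd == 0:
        return None, float("nan")
    z = (x - x.mean()) / sd
    k = int(np.argmax(z))
    return k, float(z[k])


def decode_coordinates(fits: pd.DataFrame, scheme: BarcodeScheme
                       ) -> pd.DataFrame:
    """Assign segments by z-score and decode (segment, spot) to genomic
    coordinates.  Fits failing segment assignment or with undecodable
    barcodes are dropped (counted in the log)."""
    cols = intensity_columns(fits)
    inten = fits[cols].to_numpy(dtype=np.float64)
    mean = inten.mean(axis=1, keepdims=True)
    sd = inten.std(axis=1, ddof=0)
    ok = sd > 0
    z = np.full_like(inten, np.nan)
    z[ok] = (inten[ok] - mean[ok]) / sd[ok, None]
    seg = np.where(ok, np.argmax(inten, axis=1), -1)
    zbest = np.where(ok, np.nanmax(z, axis=1), np.nan)

    coords = np.full(len(fits), -1, dtype=np.int64)
    for i, (s, spot) in enumerate(zip(seg, fits["spot_barcode_id"].to_numpy())):
        if s < 0:
            continue
        c = scheme.coordinate(int(s), int(spot))
        if c is not None:
            coords[i] = c
    dropped = int((coords < 0).sum())
    if dropped:
        logger.info("decode_coordinates: dropped %d / %d fits "
                    "(ambiguous segment or undecodable barcode)",
                    dropped, len(fits))
    out = fits.loc[coords >= 0].copy()
    out["segment_id"] = seg[coords >= 0]
    out["segment_z"] = zbest[coords >= 0]
    out["genomic_bp"] = coords[coords >= 0]
    return out.reset_index(drop=True)


def _uniqueness_fraction(coords: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of genomic coordinates with at most one fit per cluster."""
    df = pd.DataFrame({"c": coords, "k": labels})
    per = df.groupby(["c", "k"]).size().groupby("c").max()
    return float((per <= 1).mean())


def spectral_disambiguation(decoded: pd.DataFrame, k_max: int = 5,
                            quantile: float = 0.75,
                            n_neighbors: int = 10,
                            genomic_weight: float = 1.0,
                            random_state: int = 0) -> tuple[pd.DataFrame, int]:
    """Assign decoded spots to chromosome-copy traces within one region.

    Spectral clustering on standardized (x, y, z, genomic) features with an
    increasing number of clusters k = 1..k_max, stopping at the smallest k
    for which the fraction of genomic coordinates that are unambiguous
    (at most one fit per cluster) reaches ``quantile``.  Duplicates left
    within a cluster keep the fit with the highest segment z-score.

    Returns the table with ``trace_index`` and ``kept`` columns, and k.
    """
    df = decoded.reset_index(drop=True).copy()
    n = len(df)
    if n == 0:
        df["trace_index"] = np.array([], dtype=int)
        df["kept"] = np.array([], dtype=bool)
        return df, 1
    feats = df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=np.float64)
    gen = df["genomic_bp"].to_numpy(dtype=np.float64)[:, None]
    feats = np.hstack([feats, gen])
    sd = feats.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / sd
    feats[:, 3] *= genomic_weight

    coords = df["genomic_bp"].to_numpy()
    k_cap = min(k_max, n)
    labels = np.zeros(n, dtype=int)
    chosen_k = 1
    for k in range(1, k_cap + 1):
        if k == 1:
            cand = np.zeros(n, dtype=int)
        else:
            sc = SpectralClustering(
                n_clusters=k, affinity="nearest_neighbors",
                n_neighbors=min(n_neighbors, n - 1),
                assign_labels="kmeans", random_state=random_state)
            cand = sc.fit_predict(feats)
        labels, chosen_k = cand, k
        if _uniqueness_fraction(coords, cand) >= quantile:
            break
    df["trace_index"] = labels
    # resolve remaining duplicates within a cluster by highest z-score
    order = df.sort_values("segment_z", ascending=False)
    first = order.drop_duplicates(["trace_index", "genomic_bp"]).index
    df["kept"] = df.index.isin(first)
    return df, chosen_k


def qc_filter(fits: pd.DataFrame, max_fit_sd: float = np.inf,
              min_snr: float = 0.0) -> pd.DataFrame:
    """Drop fits exceeding the fit-SD threshold or below the
    signal-to-background threshold; the order of the two predicates does
    not matter."""
    keep = (fits["fit_sd_nm"] <= max_fit_sd) & (fits["snr"] >= min_snr)
    removed = int((~keep).sum())
    if removed:
        logger.info("qc_filter: removed %d / %d fits", removed, len(fits))
    return fits.loc[keep].reset_index(drop=True)
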