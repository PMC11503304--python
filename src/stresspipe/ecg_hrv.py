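"""R-R interval preprocessing and time-domain HRV features.

The preprocessing chain mirrors standard practice for chest-strap R-R
exports: (1) physiologically implausible intervals (outside 300-2000 ms)
are marked missing, (2) gaps are filled by linear interpolation, (3)
ectopic beats are removed with the Malik criterion (an interval deviating
by more than 20% from the previous accepted interval), and (4) the freshly
removed beats are interpolated again, yielding a gap-free N-N series.

HRV features are the classical time-domain set (SDNN, RMSSD, pNN50, ...)
computed per task block; blocks of roughly a minute are long enough for
the ultra-short-term subset {SDNN, RMSSD, pNN50, mean HR} to be stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

from .errors import InsufficientDataError
from .io_core import RROrigin, RRSeries, SessionManifest

log = logging.getLogger("stresspipe")

#: Features established for ultra-short-term (<5 min) HRV windows.
ULTRA_SHORT_TERM_SUBSET = ("sdnn", "rmssd", "pnni_50", "mean_hr")


@dataclass
class HRVFeatures:
    """Time-domain HRV descriptors of one N-N interval window.

    Units: ``*_nni`` fields in ms, ``pnni_*`` in percent, ``*_hr`` in
    beats/min, ``cvsd``/``cvnni`` dimensionless.
    """

    mean_nni: float
    sdnn: float
    sdsd: float
    nni_50: int
    pnni_50: float
    nni_20: int
    pnni_20: float
    rmssd: float
    median_nni: float
    range_nni: float
    cvsd: float
    cvnni: float
    mean_hr: float
    max_hr: float
    block: int | None = None
    low_quality: bool = False

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name not in ("block", "low_quality")}


def mark_rr_outliers(
    rr: RRSeries, low_ms: float = 300.0, high_ms: float = 2000.0
) -> RRSeries:
    """Replace intervals outside the closed band [low_ms, high_ms] with NaN.

    The bounds themselves are kept: only intervals strictly below ``low_ms``
    or strictly above ``high_ms`` are implausible.
    """
    iv = rr.intervals_ms.copy()
    with np.errstate(invalid="ignore"):
        bad = (iv < low_ms) | (iv > high_ms)
    iv[bad] = np.nan
    out = RRSeries(iv, origin=rr.origin, source_id=rr.source_id)
    if np.all(np.isnan(iv)):
        log.warning("%s: every R-R interval marked as outlier", rr.source_id)
    return out


def interpolate_missing(rr: RRSeries) -> RRSeries:
    """Fill missing intervals by linear interpolation against index.

    Leading/trailing gaps, where a two-sided fit is undefined, take the
    nearest present value. Requires at least two present intervals.
    """
    iv = rr.intervals_ms
    present = ~np.isnan(iv)
    if present.sum() < 2:
        raise InsufficientDataError(
            f"{rr.source_id}: need >= 2 present intervals to interpolate "
            f"(have {int(present.sum())})"
        )
    idx = np.arange(iv.size)
    filled = np.interp(idx, idx[present], iv[present])
    return RRSeries(filled, origin=RROrigin.INTERPOLATED, source_id=rr.source_id)


def remove_ectopic_malik(rr: RRSeries, tolerance: float = 0.2) -> RRSeries:
    """Mark ectopic beats with the Malik criterion.

    Scanning left to right, an interval differing from the previous
    *accepted* interval by more than ``tolerance`` x that interval is
    replaced by NaN; the reference interval does not advance past a
    rejected beat. Output origin is ``nn`` (N-N with holes to re-fill).
    """
    iv = rr.intervals_ms.copy()
    prev: float | None = None
    for i, v in enumerate(iv):
        if np.isnan(v):
            continue
        if prev is not None and abs(v - prev) > tolerance * prev:
            iv[i] = np.nan
            continue
        prev = v
    return RRSeries(iv, origin=RROrigin.NN, source_id=rr.source_id)


def preprocess_rr(rr: RRSeries, config: dict | None = None) -> RRSeries:
    """Full chain: outlier marking -> interpolate -> Malik -> interpolate."""
    from .io_core import default_config

    cfg = default_config()
    if config:
        cfg.update(config)
    step1 = mark_rr_outliers(rr, cfg["rr_low_ms"], cfg["rr_high_ms"])
    step2 = interpolate_missing(step1)
    step3 = remove_ectopic_malik(step2, cfg["malik_tolerance"])
    step4 = interpolate_missing(step3)
    return RRSeries(step4.intervals_ms, origin=RROrigin.NN, source_id=rr.source_id)


def compute_hrv_features(nn: RRSeries, block: int | None = None,
                         low_quality: bool = False) -> HRVFeatures:
    """Compute every time-domain feature from a gap-free N-N window.

    ``nni_50``/``nni_20`` count successive differences strictly greater
    than 50/20 ms; ``pnni_X`` normalizes by the number of successive
    differences. SDNN and SDSD use the sample standard deviation (n-1).
    Mean and max heart rate are taken over per-beat instantaneous rates
    60000 / NN_i.
    """
    iv = nn.intervals_ms
    if np.isnan(iv).any():
        raise InsufficientDataError(
            f"{nn.source_id}: N-N series still contains missing intervals"
        )
    if iv.size < 2:
        raise InsufficientDataError(
            f"{nn.source_id}: need >= 2 intervals for HRV features (have {iv.size})"
        )
    diffs = np.diff(iv)
    abs_diffs = np.abs(diffs)
    n_diffs = diffs.size
    hr = 60000.0 / iv
    nni_50 = int(np.sum(abs_diffs > 50.0))
    nni_20 = int(np.sum(abs_diffs > 20.0))
    mean_nni = float(iv.mean())
    sdnn = float(iv.std(ddof=1))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    return HRVFeatures(
        mean_nni=mean_nni,
        sdnn=sdnn,
        sdsd=float(diffs.std(ddof=1)) if n_diffs >= 2 else 0.0,
        nni_50=nni_50,
        pnni_50=100.0 * nni_50 / n_diffs,
        nni_20=nni_20,
        pnni_20=100.0 * nni_20 / n_diffs,
        rmssd=rmssd,
        median_nni=float(np.median(iv)),
        range_nni=float(iv.max() - iv.min()),
        cvsd=rmssd / mean_nni,
        cvnni=sdnn / mean_nni,
        mean_hr=float(hr.mean()),
        max_hr=float(hr.max()),
        block=block,
        low_quality=low_quality,
    )


def hrv_block_pipeline(
    rr: RRSeries,
    manifest: SessionManifest,
    rr_times_s: np.ndarray | None = None,
    config: dict | None = None,
) -> list[HRVFeatures]:
    """Preprocess a raw session R-R series and compute features per block.

    An interval belongs to the block whose ``[start_s, end_s)`` window
    contains the time of its terminating beat. ``rr_times_s`` defaults to
    the cumulative time of the raw series. Blocks with fewer than
    ``min_block_intervals`` intervals are flagged low-quality; blocks with
    fewer than 2 intervals are dropped with a warning.
    """
    from .io_core import default_config

    cfg = default_config()
    if config:
        cfg.update(config)
    if rr_times_s is None:
        rr_times_s = rr.cumulative_times_s()
    rr_times_s = np.asarray(rr_times_s, dtype=float)
    if rr_times_s.size != rr.intervals_ms.size:
        raise ValueError("rr_times_s length must match the interval count")

    clean = preprocess_rr(rr, cfg)
    out: list[HRVFeatures] = []
    for bw in manifest.blocks:
        in_block = (rr_times_s >= bw.start_s) & (rr_times_s < bw.end_s)
        n = int(in_block.sum())
        if n < 2:
            log.warning(
                "%s block %d: only %d intervals, skipping",
                manifest.participant_id, bw.block_index, n,
            )
            continue
        window = RRSeries(
            clean.intervals_ms[in_block], origin=RROrigin.NN,
            source_id=f"{rr.source_id}:block{bw.block_index}",
        )
        low_quality = n < cfg["min_block_intervals"]
        if low_quality:
            log.warning(
                "%s block %d: only %d intervals, flagged low-quality",
                manifest.participant_id, bw.block_index, n,
            )
        out.append(compute_hrv_features(window, block=bw.block_index,
                                        low_quality=low_quality))
    return out
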