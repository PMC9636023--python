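"""Quantitative evaluation: windowed SSIM, PSNR and the two SNR definitions.

For reporting, volumes are min-max normalized jointly (one common min and
max over the prediction/ground-truth pair) and compared with the standard
windowed SSIM (11-voxel Gaussian window, sd 1.5) and PSNR with the peak set
to the normalized ground-truth maximum. The global-moment SSIM used inside
the training loss lives in :mod:`rlnet.train`; evaluation reports can
include both. SNR of simulated noisy data is the variance ratio
10*log10(Var(S)/Var(N)); camera-data SNR uses photon statistics
S / sqrt(S + N_r^2) with S in photoelectrons.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .train import ssim_global

__all__ = ["normalize_pair", "ssim_windowed", "psnr", "snr_simulated",
           "snr_photon", "evaluate"]


def _arr(v) -> np.ndarray:
    return np.asarray(getattr(v, "data", v), dtype=np.float64)


def normalize_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalize each volume of a pair onto [0, 1].

    Metrics are computed on normalized outputs and ground truths; each
    volume is normalized by its own range so that a global scale or offset
    in the prediction does not masquerade as a structural error.
    """
    out = []
    for v in (a, b):
        v = _arr(v)
        lo, hi = v.min(), v.max()
        if hi <= lo:
            raise ValueError("degenerate volume: no intensity range to normalize")
        out.append((v - lo) / (hi - lo))
    return out[0], out[1]


def ssim_windowed(a, b, data_range: float = 1.0) -> float:
    """Mean local SSIM over sliding Gaussian windows (11 voxels, sd 1.5)."""
    a, b = _arr(a), _arr(b)
    if a.shape != b.shape:
        raise ValueError(f"dim mismatch {a.shape} vs {b.shape}")
    if min(a.shape) < 11:
        raise ValueError(f"volume {a.shape} smaller than the 11-voxel SSIM window")
    return float(structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False))


def psnr(a, b, peak: float) -> float:
    """Peak signal-to-noise ratio 10*log10(peak^2 / mse) in dB."""
    a, b = _arr(a), _arr(b)
    if a.shape != b.shape:
        raise ValueError(f"dim mismatch {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(peak ** 2 / mse))


def snr_simulated(signal, noise) -> float:
    """Variance-ratio SNR in dB of a noiseless signal vs the added noise."""
    s, n = _arr(signal), _arr(noise)
    if s.shape != n.shape:
        raise ValueError(f"dim mismatch {s.shape} vs {n.shape}")
    vn = float(np.var(n))
    if vn == 0:
        raise ValueError("noise has zero variance")
    return float(10.0 * np.log10(np.var(s) / vn))


def snr_photon(signal_counts, gain: float = 0.46, read_noise: float = 1.3,
               background: float = 0.0):
    """Photon-statistics SNR S / sqrt(S + N_r^2).

    ``signal_counts`` are digital counts; S = (counts - background) * gain
    photoelectrons, with ``gain`` in photoelectrons per count and
    ``read_noise`` in electrons. Accepts scalars or arrays.
    """
    s = (np.asarray(signal_counts, dtype=np.float64) - background) * gain
    if np.any(s < 0):
        raise ValueError("negative signal after background correction")
    out = s / np.sqrt(s + read_noise ** 2)
    return float(out) if out.ndim == 0 else out


def _pair_metrics(pred, gt, with_global: bool) -> dict:
    p, g = normalize_pair(pred, gt)
    rec = {"ssim": (ssim_windowed(p, g) if min(p.shape) >= 11
                    else float(structural_similarity(
                        p, g, data_range=1.0, gaussian_weights=True, sigma=1.5,
                        use_sample_covariance=False, win_size=min(p.shape) // 2 * 2 - 1))),
           "psnr_db": psnr(p, g, peak=float(g.max()))}
    if with_global:
        rec["ssim_global"] = ssim_global(p, g)
    return rec


def evaluate(preds: Sequence, gts: Sequence, mode: str = "per-volume",
             with_global_ssim: bool = True) -> pd.DataFrame:
    """Per-item SSIM/PSNR table with a trailing mean +/- sd summary row.

    mode "per-volume" scores each pred/gt pair as a whole; "per-slice" scores
    every z slice of every pair separately (a (D,H,W) volume yields D rows).
    """
    if len(preds) != len(gts):
        raise ValueError(f"set size mismatch: {len(preds)} preds vs {len(gts)} gts")
    if mode not in ("per-volume", "per-slice"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for idx, (p, g) in enumerate(zip(preds, gts)):
        pa, ga = _arr(p), _arr(g)
        if mode == "per-volume":
            rows.append({"item": str(idx), **_pair_metrics(pa, ga, with_global_ssim)})
        else:
            for z in range(pa.shape[0]):
                rows.append({"item": f"{idx}/z{z}",
                             **_pair_metrics(pa[z], ga[z], with_global_ssim)})
    df = pd.DataFrame(rows)
    metric_cols = [c for c in df.columns if c != "item"]
    summary = {"item": f"mean±sd (n={len(df)})"}
    for c in metric_cols:
        vals = df[c].to_numpy(dtype=float)
        summary[c] = float(np.mean(vals))
        summary[c + "_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
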