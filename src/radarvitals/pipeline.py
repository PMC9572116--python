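"""End-to-end processing chain and evaluation against reference rates.

``run_pipeline`` ties the stages together: range FFT -> static-clutter
removal -> target-bin selection -> DC-offset compensation -> extended-DACM
phase -> phase difference -> iterative VMD wavelet-interval-threshold
denoising -> respiration and heart-rate estimation with the confidence
decision rule.  Each stage logs what it chose; stage failures carry the
stage name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .denoise import DenoiseDiagnostics, WITParams, ivmd_wit
from .phase import compensate_dc, extract_phase_dacm, fit_circle_nlls, phase_difference
from .preprocess import range_fft, remove_static_clutter, select_range_bin
from .synthetic import IQFrameMatrix
from .vitals import (
    HEART_BAND,
    RESP_BAND,
    HeartDecision,
    band_peak_snr,
    bandpass_heart,
    decide_heart_rate,
    extract_heart_waveform,
    fft_confidence,
    fft_czt_rate,
    fft_spectrum,
    notch_harmonics,
    peak_interval_rate,
    relative_error,
)
from .vmd import VMDParams

__all__ = ["PipelineError", "VitalsReport", "run_pipeline", "evaluate"]

logger = logging.getLogger("radarvitals")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class VitalsReport:
    """Final rates, the heart decision record, SNRs and diagnostics."""

    resp_hz: float
    resp_bpm: float
    heart: HeartDecision
    heart_bpm: float
    snr_resp_before: float
    snr_resp_after: float
    snr_heart_before: float
    snr_heart_after: float
    bin_index: int
    denoise: DenoiseDiagnostics | None = None
    resp_err_pct: float | None = None
    heart_err_pct: float | None = None

    def to_dict(self) -> dict:
        d = {
            "resp_hz": self.resp_hz,
            "resp_bpm": self.resp_bpm,
            "heart_hz": self.heart.final,
            "heart_bpm": self.heart_bpm,
            "heart_f_fft_czt": self.heart.f_fft_czt,
            "heart_f_peek": self.heart.f_peek,
            "heart_n_peaks": self.heart.n_peaks,
            "heart_s_fft": self.heart.s_fft,
            "heart_chosen": self.heart.chosen,
            "snr_resp_before": self.snr_resp_before,
            "snr_resp_after": self.snr_resp_after,
            "snr_heart_before": self.snr_heart_before,
            "snr_heart_after": self.snr_heart_after,
            "bin_index": self.bin_index,
            "resp_err_pct": self.resp_err_pct,
            "heart_err_pct": self.heart_err_pct,
        }
        return d

    def to_json(self, **kwargs) -> str:
        d = self.to_dict()
        if self.denoise is not None:
            d["denoise"] = json.loads(self.denoise.to_json())
        return json.dumps(d, **kwargs)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 — re-raise with stage label
                raise PipelineError(name, e) from e
        return wrapped
    return deco


def run_pipeline(
    cube: IQFrameMatrix,
    wit: WITParams | None = None,
    vmd_params: VMDParams | None = None,
    conf_threshold: float = 0.4,
    diff_threshold: float = 0.1,
    resp_ref_bpm: float | None = None,
    heart_ref_bpm: float | None = None,
    window: str = "hann",
) -> VitalsReport:
    """Process one I/Q cube into a vitals report."""
    wit = wit if wit is not None else WITParams()
    vmd_params = vmd_params if vmd_params is not None else VMDParams()
    fs = cube.config.fs_slow

    @_stage("preprocess")
    def _preprocess():
        rp = remove_static_clutter(range_fft(cube, window=window))
        sel = select_range_bin(rp)
        logger.info(
            "preprocess: selected range bin %d (%.2f m), score %.3g",
            sel.bin_index, rp.bin_to_range[sel.bin_index], sel.selection_score,
        )
        return sel

    @_stage("phase_extraction")
    def _phase(sel):
        fit = fit_circle_nlls(sel.slow_time)
        logger.info(
            "phase_extraction: DC offset (%.3g, %.3g), radius %.3g, "
            "fit residual %.3g",
            fit.center_i, fit.center_q, fit.radius, fit.residual,
        )
        z = compensate_dc(sel.slow_time, fit)
        ps = extract_phase_dacm(z, fs_slow=fs)
        return phase_difference(ps)

    @_stage("denoise")
    def _denoise(diff):
        den, diag = ivmd_wit(diff.values, wit, vmd_params)
        logger.info(
            "denoise: K1=%d, K2 range %d-%d over %d iterations",
            diag.K1, min(diag.K2_per_iteration), max(diag.K2_per_iteration),
            wit.A,
        )
        return den, diag

    @_stage("vitals")
    def _vitals(raw_diff, den, diag):
        resp_spec = fft_czt_rate(den, fs, RESP_BAND)
        f_resp = resp_spec.peak_freq
        heart_sig = notch_harmonics(
            bandpass_heart(den, fs), fs, f_resp
        )
        czt = fft_czt_rate(heart_sig, fs, HEART_BAND)
        heart_wave = extract_heart_waveform(heart_sig, fs)
        n_p, f_peek = peak_interval_rate(heart_wave, fs)
        s_fft = fft_confidence(fft_spectrum(heart_sig, fs))
        decision = decide_heart_rate(
            czt.peak_freq, f_peek, s_fft,
            conf_threshold=conf_threshold,
            diff_threshold=diff_threshold,
            n_peaks=n_p,
        )
        logger.info(
            "vitals: resp %.3f Hz; heart fft_czt %.3f Hz, peek %.3f Hz "
            "(Np=%d, s_fft=%.2f) -> %s",
            f_resp, decision.f_fft_czt, decision.f_peek, n_p, s_fft,
            decision.chosen,
        )
        report = VitalsReport(
            resp_hz=f_resp,
            resp_bpm=60.0 * f_resp,
            heart=decision,
            heart_bpm=60.0 * decision.final,
            snr_resp_before=band_peak_snr(raw_diff, fs, RESP_BAND),
            snr_resp_after=band_peak_snr(den, fs, RESP_BAND),
            snr_heart_before=band_peak_snr(raw_diff, fs, HEART_BAND),
            snr_heart_after=band_peak_snr(den, fs, HEART_BAND),
            bin_index=-1,
            denoise=diag,
        )
        if resp_ref_bpm is not None:
            report.resp_err_pct = relative_error(f_resp, resp_ref_bpm)
        if heart_ref_bpm is not None:
            report.heart_err_pct = relative_error(decision.final, heart_ref_bpm)
        return report

    sel = _preprocess()
    diff = _phase(sel)
    den, diag = _denoise(diff)
    report = _vitals(diff.values, den, diag)
    report.bin_index = sel.bin_index
    return report


def evaluate(rows: pd.DataFrame, references: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Join per-run estimates with references and compute relative errors.

    ``rows`` needs columns ``id`` and ``heart_hz`` (optionally ``resp_hz``);
    ``references`` needs ``id`` and ``heart_ref_bpm`` (optionally
    ``resp_ref_bpm``).  Returns the joined table with per-run relative
    errors (%) and a summary dict of mean absolute errors.
    """
    rows = pd.DataFrame(rows)
    references = pd.DataFrame(references)
    missing = set(rows["id"]) - set(references["id"])
    if missing:
        raise ValueError(f"no reference for ids: {sorted(missing)}")
    merged = rows.merge(references, on="id", how="left", validate="one_to_one")
    merged["heart_err_pct"] = [
        relative_error(f, r)
        for f, r in zip(merged["heart_hz"], merged["heart_ref_bpm"])
    ]
    summary = {"mean_heart_err_pct": float(merged["heart_err_pct"].mean())}
    if "resp_hz" in merged.columns and "resp_ref_bpm" in merged.columns:
        merged["resp_err_pct"] = [
            relative_error(f, r)
            for f, r in zip(merged["resp_hz"], merged["resp_ref_bpm"])
        ]
        summary["mean_resp_err_pct"] = float(merged["resp_err_pct"].mean())
    return merged, summary
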