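"""Rendering of simulated FRAP image series.

Each frame is background plus the sum of compartment masks scaled by their
current concentration, followed by detector noise and an optional integer
sample drift.  Poisson noise models photon-limited confocal detection:
counts are drawn from Poisson((signal + background) * gain) and divided by
the gain, so the per-pixel SNR at intensity I is sqrt(I * gain).
"""

from __future__ import annotations

import numpy as np

from .network import CompartmentNetwork
from .series_io import FrapSeries
from .simulate import AcquisitionParams, GroundTruth

__all__ = ["render_series"]


def render_series(
    network: CompartmentNetwork,
    truth: GroundTruth,
    params: AcquisitionParams,
) -> FrapSeries:
    """Render ground-truth concentrations into an image time series.

    Returns a :class:`FrapSeries` with a float stack (quantization to 16-bit
    happens on write).  Metadata records the seed, the number of pixels that
    would clip in 16-bit output, and a ``drift_warning`` flag when drift
    pushes compartment content outside the frame.
    """
    n_frames = params.n_frames
    if truth.concentration_traces.shape[1] != n_frames:
        raise ValueError(
            "ground-truth traces and acquisition params disagree on frame count"
        )
    h, w = params.image_size
    mask_indices = [np.nonzero(c.mask) for c in network.compartments]
    rng = np.random.default_rng(params.rng_seed)

    stack = np.empty((n_frames, h, w), dtype=np.float32)
    drift_warning = False
    n_clipped = 0
    any_mask = np.zeros((h, w), dtype=bool)
    for c in network.compartments:
        any_mask |= c.mask

    for m in range(n_frames):
        frame = np.full((h, w), float(params.background_level))
        for k, idx in enumerate(mask_indices):
            frame[idx] += truth.concentration_traces[k, m]
        if params.noise_model == "poisson":
            counts = rng.poisson(np.maximum(frame, 0.0) * params.photon_gain)
            frame = counts / params.photon_gain
        elif params.noise_model == "gaussian":
            frame = frame + rng.normal(0.0, params.gaussian_sigma, size=frame.shape)
        frame = np.maximum(frame, 0.0)

        dx, dy = params.drift_per_frame
        sr, sc = int(round(m * dy)), int(round(m * dx))
        if sr or sc:
            shifted = np.full_like(frame, params.background_level)
            src_r = slice(max(0, -sr), min(h, h - sr))
            src_c = slice(max(0, -sc), min(w, w - sc))
            dst_r = slice(max(0, sr), min(h, h + sr))
            dst_c = slice(max(0, sc), min(w, w + sc))
            if src_r.start < src_r.stop and src_c.start < src_c.stop:
                shifted[dst_r, dst_c] = frame[src_r, src_c]
            lost = np.ones((h, w), dtype=bool)
            lost[src_r, src_c] = False
            if np.any(any_mask & lost):
                drift_warning = True
            frame = shifted

        n_clipped += int(np.count_nonzero(frame > 65535))
        stack[m] = frame

    return FrapSeries(
        stack=stack,
        timestamps_s=truth.timestamps_s,
        bleach_frame_index=truth.bleach_frame_index,
        source_path="synthetic",
        metadata={
            "seed": params.rng_seed,
            "noise_model": params.noise_model,
            "drift_warning": drift_warning,
            "n_clipped_16bit": n_clipped,
            "bleach_target": truth.bleach_target,
        },
    )
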