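"""From raw EMG to muscle activation.

Plants a known neural drive, draws raw EMG from the exponential
observation model, recovers the drive with the Bayesian filter, and
shapes it into activation with the asymmetric first-order dynamics.
"""

import numpy as np

from gaitmtu import ActivationConfig, activation_dynamics, estimate_drive
from gaitmtu.synthetic import gen_emg

fs = 1000.0
t = np.arange(3000) / fs
true_drive = np.where((t > 1.0) & (t < 2.0), 0.7, 0.05)

emg = gen_emg(true_drive, fs=fs, seed=7)
drive_hat = estimate_drive(emg)
activation = activation_dynamics(t, drive_hat,
                                 ActivationConfig(tau_act=0.012,
                                                  tau_deact=0.048))

on = (t > 1.2) & (t < 1.9)
off = t < 0.9
delay_ms = int(np.argmax(drive_hat[1000:] >= 0.35))
print(f"true drive plateau 0.70 -> estimated median "
      f"{np.median(drive_hat[on]):.3f}")
print(f"true baseline 0.05 -> estimated median "
      f"{np.median(drive_hat[off]):.3f}")
print(f"onset tracking delay: {delay_ms} ms "
      "(the filter lags by a few tens of ms, matching the physiological "
      "delay between EMG and force production)")
print(f"activation peak {activation.max():.3f}; the activation decays "
      "slower than it rises (tau_deact > tau_act)")
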