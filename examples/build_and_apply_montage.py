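"""Build a 29-region MEG source montage and read a simulated discharge.

Simulates a 100-nAm tangential dipole firing 20-Hz bursts at the right
frontocentral region FC6R, superposed on default-level channel noise,
then reconstructs the regional-source waveforms through the whitened,
depth-weighted inverse with 2% regularization.
"""

import numpy as np

import megmontage as mm
import megmontage.simulate as sim
from megmontage.forward import DipoleSource

# geometry: synthetic 306-channel helmet, 29 regional sources on a 70-mm shell
geom = mm.StudyGeometry.default(seed=0, grid_levels=0)
lf = mm.build_leadfield(geom.sources, geom.array, geom.sphere)
op = mm.build_montage(lf, mm.NoiseModel.from_array(geom.array), lambda_frac=0.02)
print(f"montage operator: {op.transform.shape[0]} components x {op.transform.shape[1]} channels, "
      f"Gram condition number {mm.condition_number(op):.0f}")

# simulate: 4-cycle 20-Hz bursts, one per second, 100 nAm, 2-70 Hz band
loc = geom.sources["FC6R"]
burst = sim.make_burst_waveform(sim.BurstSpec(), fs=1000.0, duration=10.0)
background = sim.synth_background(geom.array, fs=1000.0, duration=10.0, seed=11)
rec = sim.simulate_recording(
    DipoleSource(loc.position, loc.tangential_direction()), burst, background, geom.sphere
)
rec.annotations["truth"] = {"label": "FC6R", "position_m": loc.position.tolist()}

# evaluate: SNR on sensors (SNR1) and principal-orientation montage traces (SNR2)
report = mm.evaluate_recording(rec, op, geom.sources)
print(f"simulated source at {report.label}:")
print(f"  best sensor SNR1      = {report.best_snr1:5.1f} dB ({report.best_sensor})")
print(f"  best montage SNR2     = {report.best_snr2:5.1f} dB ({report.best_montage})")
print(f"  channels >= 15 dB     : Ndt1 = {report.ndt1}, Ndt2 = {report.ndt2}")
print(f"  reconstructed amplitude = {report.amplitude * 1e9:.0f} nAm (simulated 100 nAm)")
print(f"  source-to-sensor distance D1 = {report.d1 * 1e3:.0f} mm")

# The montage concentrates the discharge on the correct regional channel:
# SNR2 is comparable to SNR1 but spread over far fewer (Ndt2 << Ndt1)
# channels, which is what makes source-montage review fast.
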