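# Condition table: experimental condition label -> SimulationConfig overrides.
#
# participation_p is the per-ROI per-wave recruitment probability for each
# age / pharmacology combination (fraction of glial compartments showing a
# transient per wave).  Glutamate-sensor (iGluSnFR) sessions are imaged at
# the faster 1.7 Hz scan rate with fast sensor kinetics; calcium (GCaMP3)
# sessions at 0.74 Hz.  DL-TBOA is a glutamate-transporter blocker: with
# uptake blocked, more glutamate reaches glial membranes and recruitment
# rises, which here is simply a larger participation_p.
P7_control:
  participation_p: 0.42
  sensor: calcium
  frame_rate_hz: 0.74
  n_frames: 150
P9_control:
  participation_p: 0.48
  sensor: calcium
  frame_rate_hz: 0.74
  n_frames: 150
P11_control:
  participation_p: 0.13
  sensor: calcium
  frame_rate_hz: 0.74
  n_frames: 150
P9_TBOA:
  participation_p: 0.58
  sensor: calcium
  frame_rate_hz: 0.74
  n_frames: 150
P11_TBOA:
  participation_p: 0.61
  sensor: calcium
  frame_rate_hz: 0.74
  n_frames: 150
P9_iGluSnFR:
  participation_p: 0.38
  sensor: glutamate
  frame_rate_hz: 1.7
  n_frames: 300
P11_iGluSnFR:
  participation_p: 0.06
  sensor: glutamate
  frame_rate_hz: 1.7
  n_frames: 300
P11_iGluSnFR_TBOA:
  participation_p: 0.31
  sensor: glutamate
  frame_rate_hz: 1.7
  n_frames: 300
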