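"""Detection and hysteresis in a plain dynamic neural field.

Drives a 100-site orientation field (no learning) with a localized
Gaussian input whose amplitude ramps up and then back down, and prints
the output measure y = max_x g(u) along the way.  The interaction kernel
is used at full strength here: the field is silent at small amplitudes,
ignites once recurrent excitation can bootstrap the subthreshold output,
and on the way down the recurrent drive keeps the formed peak alive all
the way to zero input - the self-stabilized extreme of the bistable
regime.  (The simulation preset scales this
kernel to unit peak, which moves the field into the input-tracking
regime the adaptive experiments need.)
"""

import numpy as np

from dnfip import (
    DynamicsConfig,
    FieldState,
    TransferParams,
    field_step,
    make_kernel,
    output_measure,
    tactile_preset,
)

preset = tactile_preset()
kernel = make_kernel(preset.kernel, preset.grid)  # full strength, no rescaling
tp = TransferParams(1.0, -5.0)
dyn = DynamicsConfig(tau=0.1, dt=0.01)

d = np.abs(preset.grid.sites - 180.0)
d = np.minimum(d, 360.0 - d)
bump = np.exp(-(d**2) / (2 * 10.8**2))  # one contact, blurred over ~11 deg

state = FieldState(np.zeros(preset.grid.n_sites))
print("amplitude ramp (up then down), output measure y:")
amps = list(np.arange(0.0, 6.1, 0.5))
for A in amps + amps[-2::-1]:
    for _ in range(300):  # relax 3 time constants per amplitude step
        state = field_step(state, A * bump, kernel, tp, dyn, preset.grid)
    y = output_measure(state, tp)
    print(f"  S_max = {A:4.1f}   y = {y:.3f}   {'PEAK' if y > 0.5 else ''}")

print(
    "\nOn the way up the field ignites only once recurrent excitation can"
    "\nbootstrap the subthreshold output; on the way down the formed peak"
    "\nsurvives even at S_max = 0: the detection threshold strictly exceeds"
    "\nthe release threshold (hysteresis)."
)
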