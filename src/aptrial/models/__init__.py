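"""Cell-model registry entries.

The baseline biophysical model ("ORd-endo") and the fast 4-variable surrogate
("toy-fast") are registered on import of :mod:`aptrial`.
"""

from __future__ import annotations

from .. import cell_engine as ce
from . import minimal, ord

ORD_ENDO = ce.CellModelSpec(
    name="ORd-endo",
    n_states=ord.N_STATES,
    rhs=ord.rhs,
    initial_state=ord.INITIAL_STATE,
    default_protocol=ce.StimulusProtocol(
        cycle_length=1000.0,
        n_beats=150,
        stim_amplitude=ord.STIM_AMPLITUDE,
        stim_duration=ord.STIM_DURATION,
        stim_onset=0.0,
    ),
)

TOY_FAST = ce.CellModelSpec(
    name="toy-fast",
    n_states=minimal.N_STATES,
    rhs=minimal.rhs,
    initial_state=minimal.INITIAL_STATE,
    default_protocol=ce.StimulusProtocol(
        cycle_length=1000.0,
        n_beats=20,
        stim_amplitude=minimal.STIM_AMPLITUDE,
        stim_duration=minimal.STIM_DURATION,
        stim_onset=0.0,
    ),
    voltage_gain=minimal.VOLTAGE_GAIN,
    voltage_offset=minimal.VOLTAGE_OFFSET,
    inert_scalings=frozenset(
        {"g_NaL", "g_to", "g_Ks", "g_K1", "g_NCX", "g_NaK"}
    ),
    # explicit solver: the hard threshold switches of the minimal model make
    # implicit stiff steppers chatter, while the dynamics are non-stiff
    preferred_method="RK45",
)


def register_builtin_models() -> None:
    for spec in (ORD_ENDO, TOY_FAST):
        try:
            ce.register_model(spec)
        except ValueError:
            pass
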