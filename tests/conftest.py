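"""Shared reference constants for the pepsin-deferasirox test system.

The published characterisation of deferasirox binding to pepsin provides
the numeric anchors used across the suite: tri-exponential lifetime
components at three ligand ratios, Stern-Volmer and binding constants at
three temperatures, and the derived thermodynamic parameters.
"""

import pytest

# (tau1, tau2, tau3) ns and (alpha1, alpha2, alpha3) percent, per ligand ratio
LIFETIME_COMPONENTS = [
    ((1.836, 5.719, 0.474), (16.71, 76.01, 7.27)),  # no ligand
    ((1.709, 5.776, 0.360), (18.64, 75.04, 6.32)),  # 1:1
    ((1.773, 5.799, 0.425), (18.86, 74.26, 6.88)),  # 1:2
]

TEMPERATURES_K = (298.0, 304.0, 310.0)
KSV_BY_T = {298.0: 4.142e4, 304.0: 3.447e4, 310.0: 2.338e4}  # L/mol
KA_BY_T = {298.0: 8.978e4, 304.0: 4.998e4, 310.0: 1.782e4}  # L/mol
N_BY_T = {298.0: 1.073, 304.0: 1.039, 310.0: 0.972}
TAU0_NS = 4.688
DELTA_H_KJ = -103.28
DELTA_S_J = -251.12
DELTA_G_KJ = {298.0: -28.45, 304.0: -26.94, 310.0: -25.44}

# 3D-fluorescence tryptophan/tyrosine peak (ex/em nm) and its intensities
# before and after 1:1 ligand addition
EEM_PEAK_POS = (280.0, 340.0)
EEM_PEAK_BEFORE = 592.596
EEM_PEAK_AFTER = 424.454


@pytest.fixture
def ka_by_temperature():
    return dict(KA_BY_T)
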