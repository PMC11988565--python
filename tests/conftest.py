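import numpy as np
import pytest

from prmquant.peptide_chem import parse_sequence
from prmquant.prm_synth import SimConfig


# the three-peptide hydrolysate panel: (light, heavy) ProForma text and the
# printed singly-protonated m/z each must reproduce
PANEL_MZ = [
    ("HLPSYSPSP", 984.4785),
    ("HLPSYSPSPQ", 1112.5371),
    ("TIKIPAGT", 800.4876),
    ("HLPSYSPSP[Label:13C(5)15N(1)]", 990.4923),
    ("HLP[Label:13C(5)15N(1)]SYSPSPQ", 1118.5509),
]


@pytest.fixture
def panel_pair():
    """Light/heavy peptidoforms of the 9-mer used in most pipeline tests."""
    return (
        parse_sequence("HLPSYSPSP"),
        parse_sequence("HLPSYSPSP[Label:13C(5)15N(1)]"),
    )


@pytest.fixture
def quiet_sim():
    """Noise-free simulator settings: exact ratios, no saturation."""
    return SimConfig(
        noise_sd=0.0,
        response_cv=0.0,
        saturation_ceiling=np.inf,
        seed=0,
    )


@pytest.fixture
def noisy_sim():
    """Default-noise simulator (5% per-trace CV, additive floor)."""
    return SimConfig(seed=0)
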