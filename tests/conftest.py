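import pytest

from locuspipe import readthrough as rt
from locuspipe import simulate as sim
from locuspipe import threec as c3


def quantify_preset(name: str, ct_sd: float = 0.0, seed: int = 1,
                    n_technical: int = 3):
    """Generate plates for a condition preset and run the locus pipeline."""
    noise = sim.QpcrNoiseModel(ct_sd=ct_sd)
    plate, dilutions = sim.make_locus_plates(
        sim.PRESETS[name], noise, seed=seed, n_technical=n_technical)
    return rt.quantify_locus(plate, dilutions, sim.DEFAULT_ASSAY_MAP)


@pytest.fixture(scope="session")
def noise_free_quantities():
    """Noise-free locus quantities for the three condition presets."""
    return {name: quantify_preset(name) for name in sim.PRESETS}


@pytest.fixture(scope="session")
def locus_fragment_map():
    """A 13-fragment toy locus: twelve NcoI sites, ~1.2 kb spacing."""
    seq = ("ACGT" * 300 + "CCATGG") * 12 + "ACGT" * 300
    return c3.digest_sequence(seq)
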