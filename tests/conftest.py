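import numpy as np
import pytest

import p31lipid as pl
import p31lipid.simulate as sim

#: Small acquisition grid for tests that do not exercise the printed
#: processing constants; keeps autophase and fitting fast.
SMALL_PARAMS = sim.AcquisitionParams(n_complex=486)
SMALL_ZF = 4096


def synth_spectrum(
    fractions,
    resonances=None,
    mass_mg=4.0,
    noise_sigma=0.0,
    seed=0,
    params=None,
    zf=None,
    calibrate=False,
    **process_kw,
):
    """Synthesize and process a spectrum in one call (test helper)."""
    comp = pl.LipidComposition(fractions=dict(fractions))
    if resonances is None:
        resonances = sim.default_resonances(list(fractions))
    fid = pl.synthesize_fid(
        comp, resonances, params=params, mass_mg=mass_mg,
        noise_sigma=noise_sigma, seed=seed,
    )
    if zf is None:
        zf = 32768 if params is None else max(len(fid), SMALL_ZF)
    return pl.process_fid(fid, n_zero_fill=zf, calibrate=calibrate, **process_kw)


def safe_sigma(spec):
    """Noise estimate with a floor, usable on noise-free spectra."""
    return max(pl.estimate_noise(spec), 1e-9 * float(np.max(spec.real)))


@pytest.fixture(scope="session")
def library():
    return pl.load_default_library()


@pytest.fixture(scope="session")
def pc_spectrum():
    """Noise-free single-PC spectrum at full default acquisition size."""
    return synth_spectrum({"PC": 1.0})


@pytest.fixture(scope="session")
def pc_fit(pc_spectrum):
    spec = pc_spectrum
    peaks = pl.pick_peaks(spec, safe_sigma(spec))
    return pl.fit_lineshapes(spec, peaks, shape_mode="lorentzian")
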