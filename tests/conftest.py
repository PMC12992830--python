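import numpy as np
import pytest

from barriertox import bundled_panel
from barriertox.dose_response import DoseResponseSeries, four_pl
from barriertox.panel import Assay, Model


@pytest.fixture(scope="session")
def panel():
    """The bundled 17-drug reference panel (read once per session)."""
    return bundled_panel()


def make_series(top=100.0, bottom=0.0, hill=1.0, log_ic=1.0, *,
                doses=(0.0, 1.0, 5.0, 10.0, 50.0, 100.0), n_rep=4,
                noise_cv=0.0, rng=None, baseline=1.0):
    """Noise-free or multiplicative-noise series on a known 4PL curve."""
    if rng is None:
        rng = np.random.default_rng(0)
    responses = []
    for d in doses:
        mean = 100.0 if d == 0 else float(four_pl(np.log10(d), top, bottom, hill, log_ic))
        raw = baseline * mean / 100.0 * np.ones(n_rep)
        if noise_cv > 0:
            raw = raw * (1.0 + rng.normal(0.0, noise_cv, n_rep))
        responses.append(raw)
    return DoseResponseSeries(drug="synthetic", model=Model.HIEC, assay=Assay.TEER,
                              doses_uM=doses, responses=responses)
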