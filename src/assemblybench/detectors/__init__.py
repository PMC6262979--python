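"""Assembly detectors with a uniform call signature (dff, ..., seed)."""

from .ica import detect_ica
from .promax import detect_promax, NoiseModelError
from .sgc import detect_sgc
from .core import detect_core
from .svd import detect_svd

__all__ = [
    "detect_ica",
    "detect_promax",
    "detect_sgc",
    "detect_core",
    "detect_svd",
    "NoiseModelError",
    "DETECTORS",
]


def _ica_cs(dff, params=None, rng_seed=0, **kw):
    return detect_ica(dff, variant="CS", rng_seed=rng_seed, **kw)


def _ica_mp(dff, params=None, rng_seed=0, **kw):
    return detect_ica(dff, variant="MP", rng_seed=rng_seed, **kw)


def _promax_mp(dff, params=None, rng_seed=0, **kw):
    return detect_promax(dff, variant="MP", params=params, rng_seed=rng_seed, **kw)


def _promax_cs(dff, params=None, rng_seed=0, **kw):
    return detect_promax(dff, variant="CS", params=params, rng_seed=rng_seed, **kw)


def _sgc(dff, params=None, rng_seed=0, **kw):
    return detect_sgc(dff, rng_seed=rng_seed, **kw)


def _core(dff, params=None, rng_seed=0, **kw):
    return detect_core(dff, params=params, rng_seed=rng_seed, **kw)


def _svd(dff, params=None, rng_seed=0, **kw):
    return detect_svd(dff, params=params, rng_seed=rng_seed, **kw)


#: Registry used by the sweep harness and the CLI.
DETECTORS = {
    "ICA-CS": _ica_cs,
    "ICA-MP": _ica_mp,
    "Promax-MP": _promax_mp,
    "Promax-CS": _promax_cs,
    "SGC": _sgc,
    "CORE": _core,
    "SVD": _svd,
}
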