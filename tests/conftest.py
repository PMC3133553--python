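import numpy as np
import pytest

from swpa import MassSpectrum, Peak, PeakList


def spec(d: dict[int, float]) -> MassSpectrum:
    mzs = sorted(d)
    return MassSpectrum(mz=tuple(mzs), intensity=tuple(float(d[m]) for m in mzs))


def peak(rt1=0.0, rt2=0.0, s=None, label=None, area=None) -> Peak:
    return Peak(rt1=rt1, rt2=rt2, spectrum=s or spec({50: 10, 60: 20}), label=label, area=area)


def random_spectrum(rng: np.random.Generator, n_bins=8, mz_lo=10, mz_hi=200) -> MassSpectrum:
    mz = np.sort(rng.choice(np.arange(mz_lo, mz_hi + 1), size=n_bins, replace=False))
    inten = 10.0 ** rng.uniform(1, 4, size=n_bins)
    return MassSpectrum(mz=tuple(int(m) for m in mz), intensity=tuple(inten))


def random_peaklist(rng: np.random.Generator, n: int, name="run") -> PeakList:
    peaks = [
        Peak(
            rt1=float(rng.uniform(60, 3000)),
            rt2=float(rng.uniform(0.5, 4.5)),
            spectrum=random_spectrum(rng),
            label=f"P{i}",
            area=float(rng.uniform(1e3, 1e6)),
        )
        for i in range(n)
    ]
    return PeakList(peaks=peaks, name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
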