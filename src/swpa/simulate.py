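"""Seeded synthetic GCxGC-MS peak-list pairs with known ground truth.

Real two-dimensional chromatograms of the kind this package aligns carry
~75 peaks for a standards mixture (or ~450 for a plasma extract), fragment
spectra on nominal-mass bins over 10-750 m/z, and retention times that drift
between runs — slightly for repeat injections under one method (homogeneous
runs), systematically and nonlinearly when the temperature gradient changes
(heterogeneous runs). The generator emulates exactly those features:

* a labeled reference list with sparse random fragment spectra;
* a target derived from it by a retention-time shift model, Gaussian jitter,
  multiplicative log-normal intensity noise with low-intensity bin dropout,
  and independent peak dropout — with the surviving shared labels as truth.

The ``smooth_monotone`` shift is a logistic ramp driven by the combined
elution coordinate rt1+rt2, so it is nonlinear in retention time yet
preserves the elution order of surviving compounds exactly;
``order_breaking`` deliberately swaps a fraction of adjacent compounds to
stress the method's standing elution-order assumption.

Everything is driven by numpy Generators seeded from ``SimConfig.seed``;
output is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .evaluate import TruthSet, build_truth
from .peaks import MassSpectrum, Peak, PeakList, order_peaklist

__all__ = ["SimConfig", "generate_reference", "derive_target", "generate_pair_set"]

ShiftModel = Literal["none", "affine", "smooth_monotone", "order_breaking"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic reference/target pair.

    Defaults mirror a standards-mixture run: 75 compounds over a ~50-minute
    primary ramp (seconds), a 5-second modulation window, 20-fragment spectra
    on 10-750 m/z, half-second retention jitter, moderate spectral noise and
    10% peak dropout per list.
    """

    n_compounds: int = 75
    rt1_range: tuple[float, float] = (60.0, 3060.0)
    rt2_range: tuple[float, float] = (0.5, 4.5)
    spectrum_bins: tuple[int, int] = (10, 750)
    peaks_per_spectrum: int = 20
    shift_model: ShiftModel = "none"
    shift_magnitude: float = 60.0
    rt_jitter_sd: float = 0.5
    intensity_noise_sd: float = 0.25
    bin_dropout: float = 0.05
    dropout_ref: float = 0.1
    dropout_target: float = 0.1
    order_break_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.spectrum_bins
        if self.peaks_per_spectrum > hi - lo + 1:
            raise ValueError("more spectrum peaks requested than available m/z bins")
        if not (0 <= self.dropout_ref < 1 and 0 <= self.dropout_target < 1):
            raise ValueError("dropout fractions must lie in [0, 1)")
        if self.rt1_range[0] >= self.rt1_range[1] or self.rt2_range[0] >= self.rt2_range[1]:
            raise ValueError("retention-time ranges must be non-degenerate")


def _random_spectrum(rng: np.random.Generator, cfg: SimConfig) -> MassSpectrum:
    lo, hi = cfg.spectrum_bins
    mz = np.sort(rng.choice(np.arange(lo, hi + 1), size=cfg.peaks_per_spectrum, replace=False))
    # log-uniform intensities over three decades, as fragment abundances span
    intensity = 10.0 ** rng.uniform(2.0, 5.0, size=cfg.peaks_per_spectrum)
    return MassSpectrum(mz=tuple(int(m) for m in mz), intensity=tuple(intensity))


def generate_reference(cfg: SimConfig) -> PeakList:
    """Labeled, elution-ordered reference list of ``n_compounds`` peaks."""
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.n_compounds
    rt1 = rng.uniform(*cfg.rt1_range, size=n)
    rt2 = rng.uniform(*cfg.rt2_range, size=n)
    peaks = [
        Peak(
            rt1=float(rt1[i]),
            rt2=float(rt2[i]),
            spectrum=_random_spectrum(rng, cfg),
            label=f"CMP{i:04d}",
            area=float(10.0 ** rng.uniform(3.0, 6.0)),
        )
        for i in range(n)
    ]
    return order_peaklist(PeakList(peaks=peaks, name=f"ref-seed{cfg.seed}"))


def _shift_rt(peak: Peak, cfg: SimConfig, rt_lo: float, rt_hi: float) -> tuple[float, float]:
    """Systematic retention shift as a function of the combined elution axis."""
    s = peak.rt_sum
    span = rt_hi - rt_lo
    frac = (s - rt_lo) / span if span > 0 else 0.0
    if cfg.shift_model == "none":
        return peak.rt1, peak.rt2
    if cfg.shift_model == "affine":
        d1 = cfg.shift_magnitude * (0.25 + 0.75 * frac)
    else:  # smooth_monotone and order_breaking share the nonlinear ramp
        d1 = cfg.shift_magnitude / (1.0 + np.exp(-8.0 * (frac - 0.5)))
    # secondary-column drift scales with the primary shift but stays small;
    # both shifts depend on the combined axis only, so the total shift is a
    # monotone function of rt1+rt2 and survivor elution order is preserved
    d2 = 0.001 * d1
    return peak.rt1 + d1, peak.rt2 + d2


def _corrupt_spectrum(sp: MassSpectrum, cfg: SimConfig, rng: np.random.Generator) -> MassSpectrum:
    inten = np.asarray(sp.intensity) * rng.lognormal(0.0, cfg.intensity_noise_sd, len(sp.mz))
    if cfg.bin_dropout > 0 and len(sp.mz) > 2:
        # weaker fragments vanish first under noise: drop probability decays
        # with relative intensity
        p = cfg.bin_dropout * (1.0 - inten / inten.max())
        keep = rng.random(len(sp.mz)) >= p
        if keep.sum() >= 2:
            return MassSpectrum(
                mz=tuple(m for m, k in zip(sp.mz, keep) if k),
                intensity=tuple(float(v) for v, k in zip(inten, keep) if k),
            )
    return MassSpectrum(mz=sp.mz, intensity=tuple(float(v) for v in inten))


def _thin(pl: PeakList, fraction: float, rng: np.random.Generator) -> PeakList:
    if fraction <= 0:
        return pl
    keep = rng.random(len(pl)) >= fraction
    if not keep.any():  # never emit an empty list
        keep[rng.integers(len(pl))] = True
    return PeakList(peaks=[p for p, k in zip(pl.peaks, keep) if k], name=pl.name)


def _derive(
    pool: PeakList, cfg: SimConfig, rng: np.random.Generator, name: str
) -> PeakList:
    """Shift, jitter, corrupt and thin a copy of ``pool`` into a target list."""
    sums = [p.rt_sum for p in pool]
    rt_lo, rt_hi = min(sums), max(sums)
    shifted: list[Peak] = []
    for p in pool:
        rt1, rt2 = _shift_rt(p, cfg, rt_lo, rt_hi)
        rt1 = max(0.0, rt1 + rng.normal(0.0, cfg.rt_jitter_sd))
        rt2 = max(0.0, rt2 + rng.normal(0.0, cfg.rt_jitter_sd / 50.0))
        shifted.append(
            Peak(rt1=rt1, rt2=rt2, spectrum=_corrupt_spectrum(p.spectrum, cfg, rng),
                 label=p.label, area=p.area)
        )
    if cfg.shift_model == "order_breaking" and len(shifted) > 1:
        shifted.sort(key=lambda p: p.rt_sum)
        n_swaps = int(round(cfg.order_break_fraction * (len(shifted) - 1)))
        idx = rng.choice(len(shifted) - 1, size=min(n_swaps, len(shifted) - 1), replace=False)
        for i in idx:
            a, b = shifted[i], shifted[i + 1]
            # exchange retention coordinates so compound order inverts locally
            shifted[i] = Peak(rt1=b.rt1, rt2=b.rt2, spectrum=a.spectrum, label=a.label, area=a.area)
            shifted[i + 1] = Peak(rt1=a.rt1, rt2=a.rt2, spectrum=b.spectrum, label=b.label, area=b.area)
    target = _thin(PeakList(peaks=shifted, name=name), cfg.dropout_target, rng)
    return order_peaklist(target)


def derive_target(ref: PeakList, cfg: SimConfig) -> tuple[PeakList, TruthSet]:
    """Derive a target list from a reference and return it with its truth.

    Truth indices refer to positions in the elution-ordered lists (the
    reference is re-ordered internally if needed).
    """
    rng = np.random.default_rng([cfg.seed, 1])
    ref = order_peaklist(ref)
    target = _derive(ref, cfg, rng, name=f"target-seed{cfg.seed}")
    return target, build_truth(ref, target)


def generate_pair_set(
    cfg: SimConfig, n_pairs: int, mode: Literal["homogeneous", "heterogeneous"]
) -> list[tuple[PeakList, PeakList, TruthSet]]:
    """Independent seeded (reference, target, truth) pairs for a batch study.

    Each pair draws its own compound pool; reference and target are thinned
    independently from the pool so both orphan-reference and orphan-target
    peaks occur. Homogeneous mode keeps the configured (small) jitter with no
    systematic shift; heterogeneous mode applies smooth monotone nonlinear
    shifts whose magnitudes cycle over a 30-120 s ladder, emulating runs
    acquired under different temperature gradients.
    """
    ladder = (30.0, 60.0, 90.0, 120.0)
    out = []
    for p in range(n_pairs):
        pair_seed = cfg.seed + 1000 * (p + 1)
        if mode == "homogeneous":
            pair_cfg = replace(cfg, seed=pair_seed, shift_model="none")
        else:
            pair_cfg = replace(
                cfg,
                seed=pair_seed,
                shift_model="smooth_monotone",
                shift_magnitude=ladder[p % len(ladder)],
            )
        pool = generate_reference(pair_cfg)
        rng_ref = np.random.default_rng([pair_seed, 2])
        ref = order_peaklist(_thin(pool, pair_cfg.dropout_ref, rng_ref))
        ref.name = f"ref-{p}"
        rng_tgt = np.random.default_rng([pair_seed, 1])
        target = _derive(pool, pair_cfg, rng_tgt, name=f"target-{p}")
        out.append((ref, target, build_truth(ref, target)))
    return out
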