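"""Companion measurement rules: ERG b-wave, visual water-task thresholds,
ΔΔCt relative quantification, and densitometry normalisation.

These are the small bespoke reductions used alongside the cone counts:
flash electroretinogram b-wave amplitude measured baseline-to-peak after
5-trace averaging; visual acuity / contrast-sensitivity thresholds at the
70%-success criterion of the visual water task; relative transcript
quantification by 2^(−ΔΔCt) against a reference gene and a calibrator
group; and blot band densities normalised to a loading control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ParameterError

__all__ = [
    "ErgTrace",
    "PsychometricSeries",
    "QpcrMeasurement",
    "DdctResult",
    "average_traces",
    "bwave_amplitude",
    "perception_threshold",
    "ddct_rq",
    "densitometry_normalize",
    "group_percent_difference",
]

N_TRACES_PER_LUMINANCE = 5          # averaging depth per flash luminance
SUCCESS_CRITERION = 0.70            # "above 70% of the trials"
DEFAULT_BASELINE_MS = 20.0          # pre-flash window for the b-wave baseline
CT_SD_FLAG = 0.5                    # replicate-spread QC cut-off (cycles)


@dataclass
class ErgTrace:
    """One flash-ERG sweep: voltage samples (µV) at a fixed interval.

    ``stimulus_onset`` (ms) splits the sweep into a pre-flash baseline
    window and the response; ``baseline_window`` defaults to the
    ``DEFAULT_BASELINE_MS`` ms immediately preceding the flash.
    """

    samples: np.ndarray               # µV
    dt: float                         # ms per sample (0.25-0.5 ms typical)
    flash_luminance: float            # cd·s/m²
    stimulus_onset: float = 0.0       # ms
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.baseline_window is None:
            self.baseline_window = (
                max(self.stimulus_onset - DEFAULT_BASELINE_MS, 0.0),
                self.stimulus_onset,
            )
        b0, b1 = self.baseline_window
        if b1 > self.stimulus_onset or b0 >= b1:
            raise ParameterError("baseline_window must precede stimulus onset")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt


def average_traces(traces: list[ErgTrace]) -> ErgTrace:
    """Pointwise mean of the repeated sweeps at one flash luminance.

    Exactly ``N_TRACES_PER_LUMINANCE`` traces of equal length, sampling
    interval and luminance are required.
    """
    if len(traces) != N_TRACES_PER_LUMINANCE:
        raise ParameterError(
            f"expected {N_TRACES_PER_LUMINANCE} traces per luminance, "
            f"got {len(traces)}"
        )
    first = traces[0]
    for t in traces[1:]:
        if t.samples.size != first.samples.size:
            raise ParameterError("traces differ in length")
        if t.dt != first.dt or t.flash_luminance != first.flash_luminance:
            raise ParameterError("traces differ in dt or flash luminance")
    mean = np.mean([t.samples for t in traces], axis=0)
    return ErgTrace(
        samples=mean,
        dt=first.dt,
        flash_luminance=first.flash_luminance,
        stimulus_onset=first.stimulus_onset,
        baseline_window=first.baseline_window,
    )


def bwave_amplitude(trace: ErgTrace) -> float:
    """b-wave amplitude (µV): post-stimulus peak minus the baseline mean.

    Signed: negative if the sweep never rises above its baseline.  Invariant
    to adding a constant offset to the whole trace.
    """
    t = trace.times
    b0, b1 = trace.baseline_window
    base_sel = (t >= b0) & (t < b1) if b1 > b0 else slice(0, 1)
    baseline = trace.samples[base_sel]
    if baseline.size == 0:
        baseline = trace.samples[:1]
    post = trace.samples[t >= trace.stimulus_onset]
    if post.size == 0:
        raise ParameterError("no samples after stimulus onset")
    return float(post.max() - baseline.mean())


@dataclass
class PsychometricSeries:
    """Success counts of the visual water task across stimulus levels.

    ``direction='highest_passing'`` suits acuity (harder = higher spatial
    frequency); ``'lowest_passing'`` suits contrast sensitivity (harder =
    lower contrast).
    """

    levels: np.ndarray                # strictly monotone stimulus values
    trials: np.ndarray
    successes: np.ndarray
    direction: str = "highest_passing"

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.trials = np.asarray(self.trials, dtype=int)
        self.successes = np.asarray(self.successes, dtype=int)
        if self.direction not in ("highest_passing", "lowest_passing"):
            raise ParameterError(f"unknown direction {self.direction!r}")
        if not (self.levels.size == self.trials.size == self.successes.size):
            raise ParameterError("levels, trials, successes must align")
        if self.levels.size == 0:
            raise ParameterError("at least one tested level required")
        d = np.diff(self.levels)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ParameterError("levels must be strictly monotone")
        if np.any(self.successes < 0) or np.any(self.successes > self.trials):
            raise ParameterError("require 0 <= successes <= trials")

    @property
    def rates(self) -> np.ndarray:
        return self.successes / np.maximum(self.trials, 1)


def perception_threshold(
    series: PsychometricSeries, criterion: float = SUCCESS_CRITERION
) -> float | None:
    """Threshold stimulus level at the strict >criterion success rule.

    Scanning from the easiest level toward the hardest, the threshold is
    the most extreme level still passed (success rate strictly above the
    criterion) before the first failure — so every easier tested level must
    also pass.  Returns ``None`` when even the easiest level fails.
    """
    if not 0 <= criterion < 1:
        raise ParameterError("criterion must lie in [0, 1)")
    levels = series.levels
    rates = series.rates
    # order from easy to hard
    if series.direction == "highest_passing":      # acuity: low freq is easy
        order = np.argsort(levels)
    else:                                          # contrast: high contrast is easy
        order = np.argsort(levels)[::-1]
    threshold: float | None = None
    for idx in order:
        if rates[idx] > criterion:
            threshold = float(levels[idx])
        else:
            break
    return threshold


@dataclass
class QpcrMeasurement:
    """Triplicate cycle-threshold readings of one gene in one sample."""

    sample_id: str
    group: str                        # 'EE', 'ST' or 'WT'
    gene: str
    ct_replicates: np.ndarray         # exactly 3 Ct values
    reference_gene: str = "GAPDH"

    def __post_init__(self) -> None:
        self.ct_replicates = np.asarray(self.ct_replicates, dtype=float).ravel()
        if self.ct_replicates.size != 3:
            raise ParameterError("exactly triplicate Ct values required")
        if np.any(self.ct_replicates <= 0):
            raise ParameterError("Ct values must be positive")

    @property
    def mean_ct(self) -> float:
        return float(self.ct_replicates.mean())

    @property
    def ct_sd(self) -> float:
        return float(self.ct_replicates.std(ddof=1))


@dataclass
class DdctResult:
    """Relative quantity with its intermediate ΔCt/ΔΔCt values."""

    dct: float
    ddct: float
    rq: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def ddct_rq(
    target: QpcrMeasurement,
    reference: QpcrMeasurement,
    calibrator_dct: float,
    sd_cutoff: float = CT_SD_FLAG,
) -> DdctResult:
    """Relative quantification by the delta-delta Ct method.

    ΔCt = mean target Ct − mean reference Ct; ΔΔCt = ΔCt − calibrator ΔCt
    (the calibrator ΔCt comes from the normalising group, e.g. standard
    housing); Rq = 2^(−ΔΔCt).  Replicate spread above ``sd_cutoff`` cycles
    flags the result without dropping it.
    """
    if target.sample_id != reference.sample_id:
        raise ParameterError(
            "target and reference Cts must come from the same sample"
        )
    flags = []
    if target.ct_sd > sd_cutoff or reference.ct_sd > sd_cutoff:
        flags.append("replicate_sd")
    dct = target.mean_ct - reference.mean_ct
    ddct = dct - calibrator_dct
    return DdctResult(dct=dct, ddct=ddct, rq=float(2.0 ** (-ddct)),
                      flags=tuple(flags))


def densitometry_normalize(band: float, loading_control: float) -> float:
    """Blot band density normalised to its loading-control band."""
    if loading_control <= 0:
        raise ParameterError("loading control density must be positive")
    if band < 0:
        raise ParameterError("band density must be non-negative")
    return band / loading_control


def group_percent_difference(group_mean: float, control_mean: float) -> float:
    """Percent difference of group means, e.g. +35.0 for 1.35 vs 1.00."""
    if control_mean <= 0:
        raise ParameterError("control mean must be positive")
    return 100.0 * (group_mean - control_mean) / control_mean
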