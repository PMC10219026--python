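"""TBP-promoter affinity estimation from sequence.

The model follows the three-stage picture of TBP-promoter complex
formation: (i) TBP slides along the promoter duplex (a nonspecific,
composition-driven interaction), (ii) it stops at a potential binding
site (a TATA-box position-weight-matrix match), and (iii) the duplex
bends by ~90 degrees, locking the complex (a dinucleotide bend-propensity
property of the site).  The three stages are scored by three sequence
terms and combined linearly on the -ln(Kd) scale, Kd in mol/L:

    -ln(Kd) = b0 + b_slide * slide + b_stop * stop + b_bend * bend

where ``stop`` is the best (maximal) PWM window score over the promoter
and ``bend`` is evaluated on that best window.  Lower Kd means higher
affinity and higher predicted expression of the downstream gene.

Coefficients are data, not code: the default set is obtained by
least-squares calibration against six published worked-example Kd values
(two promoters, ancestral plus minor alleles); see
:func:`calibrate_coefficients` and :func:`default_coefficients`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .sequence_io import PromoterSequence, SequenceError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

KD_NM_PER_MOLAR = 1e9
#: default relative standard error of a Kd estimate (fraction of Kd);
#: matches the dispersion band of the published worked-example estimates
DEFAULT_RELATIVE_SE = 0.10


class ModelError(ValueError):
    """Invalid model configuration or input."""


class CalibrationError(ModelError):
    """Calibration impossible on the provided examples."""


def _data_path(name: str) -> Path:
    return Path(str(resources.files("tatascan").joinpath("data", name)))


def _read_table(name_or_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(name_or_path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# PWM


@dataclass(frozen=True)
class TataPwm:
    """A TATA-box position weight matrix (log-ratio scores over ACGT)."""

    weights: np.ndarray  # width x 4
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[1] != 4:
            raise ModelError("PWM weights must be a width x 4 matrix")
        if w.shape[0] < 6:
            raise ModelError("PWM width must be at least 6")
        if not np.all(np.isfinite(w)):
            raise ModelError("PWM weights must be finite")
        if any(len(set(row)) < 2 for row in w.tolist()):
            raise ModelError("degenerate PWM row: all four bases equally scored")

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))

    @property
    def frequencies(self) -> np.ndarray:
        """Per-position base probabilities implied by the log-ratio scores."""
        f = np.exp(self.weights) * 0.25
        return f / f.sum(axis=1, keepdims=True)

    @classmethod
    def from_frequencies(cls, freqs: np.ndarray, provenance: str = "unspecified") -> "TataPwm":
        freqs = np.asarray(freqs, dtype=float)
        return cls(weights=np.log(freqs / 0.25), provenance=provenance)


def load_pwm(path: str | Path, provenance: Optional[str] = None) -> TataPwm:
    """Load a PWM config TSV with columns ``position A C G T`` (frequencies)."""
    df = _read_table(path).sort_values("position")
    freqs = df[list(BASES)].to_numpy(dtype=float)
    return TataPwm.from_frequencies(freqs, provenance=provenance or str(path))


@lru_cache(maxsize=1)
def default_pwm() -> TataPwm:
    return load_pwm(_data_path("tata_pwm.tsv"), provenance="tatascan-default-v1")


def _encode(sequence: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in sequence], dtype=np.int64)


def pwm_site_score(window: str, pwm: TataPwm) -> float:
    """Additive PWM score of a window of exactly the PWM's width."""
    if len(window) != pwm.width:
        raise ModelError(f"window length {len(window)} != PWM width {pwm.width}")
    idx = _encode(window.upper())
    if (idx < 0).any():
        raise ModelError(f"non-ACGT base in window {window!r}")
    return float(pwm.weights[np.arange(pwm.width), idx].sum())


# ---------------------------------------------------------------------------
# Slide and bend terms


@lru_cache(maxsize=1)
def _slide_table() -> dict[str, float]:
    df = _read_table(_data_path("slide_dinucleotides.tsv"))
    return dict(zip(df["dinucleotide"], df["delta_g"]))


@lru_cache(maxsize=1)
def _bend_table() -> dict[str, float]:
    df = _read_table(_data_path("bend_dinucleotides.tsv"))
    return dict(zip(df["dinucleotide"], df["bend"]))


def slide_term(sequence: str) -> float:
    """Whole-region dinucleotide composition statistic for the sliding stage.

    Defined as minus the mean nearest-neighbour duplex stability (kcal/mol)
    over all adjacent dinucleotides: AT-rich, weakly stacked promoters score
    lower, G/C-rich ones higher.  Dinucleotides containing non-ACGT bases
    are ignored.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ModelError("slide term needs a sequence of at least 2 nt")
    table = _slide_table()
    values = [table[seq[i : i + 2]] for i in range(len(seq) - 1) if seq[i : i + 2] in table]
    if not values:
        raise ModelError("no scorable dinucleotide in sequence")
    return -float(np.mean(values))


def bend_term(window: str) -> float:
    """Dinucleotide bend-propensity sum over a candidate binding site."""
    seq = window.upper()
    if len(seq) < 2:
        raise ModelError("bend term needs a window of at least 2 nt")
    table = _bend_table()
    try:
        return float(sum(table[seq[i : i + 2]] for i in range(len(seq) - 1)))
    except KeyError as exc:
        raise ModelError(f"non-ACGT base in window {window!r}") from exc


# ---------------------------------------------------------------------------
# Coefficients and estimates


@dataclass(frozen=True)
class ModelCoefficients:
    """Linear combination weights on the -ln(Kd) scale (Kd in mol/L).

    ``se_model`` is either a relative-SE fraction applied to Kd
    (``se_kind='relative'``, the default) or an absolute SE in ln-units
    (``se_kind='ln'``); both give ``se_nM = kd_nM * se_ln``.
    """

    intercept: float
    w_slide: float
    w_stop: float
    w_bend: float
    se_model: float = DEFAULT_RELATIVE_SE
    se_kind: str = "relative"
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for name in ("intercept", "w_slide", "w_stop", "w_bend"):
            if not math.isfinite(getattr(self, name)):
                raise ModelError(f"non-finite coefficient {name}")
        if not self.se_model > 0:
            raise ModelError("se_model must be positive")
        if self.se_kind not in ("relative", "ln"):
            raise ModelError(f"unknown se_kind {self.se_kind!r}")


@dataclass(frozen=True)
class AffinityEstimate:
    """-ln(Kd) with standard error, plus the derived nM-scale values."""

    minus_ln_kd: float
    se_ln: float
    best_site_start: int  # TSS-relative position of the best window's first base
    best_site_sequence: str
    kd_nM: float = field(init=False)
    se_nM: float = field(init=False)

    def __post_init__(self) -> None:
        kd = math.exp(-self.minus_ln_kd) * KD_NM_PER_MOLAR
        object.__setattr__(self, "kd_nM", kd)
        object.__setattr__(self, "se_nM", kd * self.se_ln)
        if not (self.kd_nM > 0 and self.se_nM > 0):
            raise ModelError("Kd and its SE must be positive")

    @classmethod
    def from_nM(cls, kd_nM: float, se_nM: float) -> "AffinityEstimate":
        """Build an estimate from published nM-scale values (delta method:
        se_ln = se_nM / kd_nM)."""
        return cls(
            minus_ln_kd=-math.log(kd_nM / KD_NM_PER_MOLAR),
            se_ln=se_nM / kd_nM,
            best_site_start=0,
            best_site_sequence="",
        )


def window_profiles(
    promoter: PromoterSequence, pwm: TataPwm
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window (PWM score, bend propensity, validity) over all windows of
    the PWM's width.  Windows containing ambiguity codes are invalid and
    masked out of the site search."""
    if promoter.length < pwm.width:
        raise ModelError(
            f"promoter {promoter.transcript_id} shorter than PWM width {pwm.width}"
        )
    idx = _encode(promoter.sequence)
    windows = np.lib.stride_tricks.sliding_window_view(idx, pwm.width)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        raise ModelError(f"{promoter.transcript_id}: no window free of ambiguity codes")
    scores = pwm.weights[np.arange(pwm.width)[None, :], np.clip(windows, 0, 3)].sum(axis=1)
    table = _bend_table()
    steps = np.array(
        [
            table.get(promoter.sequence[i : i + 2], 0.0)
            for i in range(promoter.length - 1)
        ]
    )
    csum = np.concatenate([[0.0], np.cumsum(steps)])
    bends = csum[pwm.width - 1 :] - csum[: promoter.length - pwm.width + 1]
    return scores, bends, valid


def best_site(
    promoter: PromoterSequence, pwm: TataPwm, coef: "ModelCoefficients"
) -> Tuple[int, float, float]:
    """The highest-affinity (minimal-Kd) window: the one maximizing the
    site-dependent part of the model, w_stop * score + w_bend * bend.
    Ties break toward the most upstream window.  Returns (index, score,
    bend)."""
    scores, bends, valid = window_profiles(promoter, pwm)
    value = np.where(valid, coef.w_stop * scores + coef.w_bend * bends, -np.inf)
    best = int(value.argmax())  # argmax takes the first (most upstream) tie
    return best, float(scores[best]), float(bends[best])


def _model_features(
    promoter: PromoterSequence, pwm: TataPwm, coef: "ModelCoefficients"
) -> Tuple[float, float, float, int, str]:
    """(slide, stop score, bend, index, window string) at the best site."""
    best, score, bend = best_site(promoter, pwm, coef)
    return (
        slide_term(promoter.sequence),
        score,
        bend,
        best,
        promoter.sequence[best : best + pwm.width],
    )


def estimate_affinity(
    promoter: PromoterSequence,
    pwm: Optional[TataPwm] = None,
    coef: Optional[ModelCoefficients] = None,
    *,
    fixed_site: Optional[int] = None,
) -> AffinityEstimate:
    """Estimate TBP affinity for a promoter.

    By default every window is scanned and the reported estimate
    corresponds to the highest-affinity (minimal Kd) window.  Passing
    ``fixed_site`` (a TSS-relative window start) pins the evaluation to
    that one window instead — a sensitivity mode for promoters with an
    annotated box.
    """
    pwm = pwm or default_pwm()
    coef = coef if coef is not None else default_coefficients()
    if fixed_site is not None:
        i = promoter.tss_to_index(fixed_site)
        if i > promoter.length - pwm.width:
            raise ModelError(
                f"fixed site {fixed_site} leaves no room for a "
                f"{pwm.width}-nt window in {promoter.transcript_id}"
            )
        window = promoter.sequence[i : i + pwm.width]
        slide, stop, bend, best_idx, best_window = (
            slide_term(promoter.sequence),
            pwm_site_score(window, pwm),
            bend_term(window),
            i,
            window,
        )
    else:
        slide, stop, bend, best_idx, best_window = _model_features(promoter, pwm, coef)
    minus_ln_kd = (
        coef.intercept + coef.w_slide * slide + coef.w_stop * stop + coef.w_bend * bend
    )
    return AffinityEstimate(
        minus_ln_kd=minus_ln_kd,
        se_ln=coef.se_model,  # identical on both scales; see ModelCoefficients
        best_site_start=promoter.index_to_tss(best_idx),
        best_site_sequence=best_window,
    )


# ---------------------------------------------------------------------------
# Calibration


@dataclass(frozen=True)
class CalibrationResult:
    coefficients: ModelCoefficients
    residuals_ln: np.ndarray  # observed - fitted, on the -ln(Kd) scale
    fitted_kd_nM: np.ndarray


def calibrate_coefficients(
    examples: Sequence[Tuple[str, float]],
    pwm: Optional[TataPwm] = None,
    *,
    se_model: float = DEFAULT_RELATIVE_SE,
) -> CalibrationResult:
    """Least-squares fit of the model coefficients to worked examples.

    ``examples`` are ``(sequence, kd_nM)`` pairs; at least four are needed
    and their feature matrix must have full rank (insufficiently varied
    examples raise :class:`CalibrationError`).  The stop and bend weights
    are constrained to be non-negative: a stronger site match or a more
    bendable site can only increase affinity under the three-stage model.

    Because the best (minimal-Kd) window itself depends on the stop and
    bend weights, the fit alternates between window selection and
    coefficient estimation until the selected windows stop changing
    (initial selection by PWM score alone).
    """
    from scipy.optimize import lsq_linear

    pwm = pwm or default_pwm()
    if len(examples) < 4:
        raise CalibrationError("calibration needs at least 4 worked examples")
    promoters = [
        PromoterSequence(gene_symbol="cal", transcript_id=f"cal{i}", sequence=seq)
        for i, (seq, _) in enumerate(examples)
    ]
    y = np.asarray([-math.log(kd / KD_NM_PER_MOLAR) for _, kd in examples])
    slides = np.asarray([slide_term(p.sequence) for p in promoters])
    profiles = [window_profiles(p, pwm) for p in promoters]

    coef = ModelCoefficients(0.0, 0.0, 1.0, 0.0)  # initial ranking: score only
    prev_choice = None
    for _ in range(25):
        choice = []
        for scores, bends, valid in profiles:
            value = np.where(valid, coef.w_stop * scores + coef.w_bend * bends, -np.inf)
            choice.append(int(value.argmax()))
        X = np.column_stack(
            [
                np.ones(len(examples)),
                slides,
                [profiles[i][0][c] for i, c in enumerate(choice)],
                [profiles[i][1][c] for i, c in enumerate(choice)],
            ]
        )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise CalibrationError(
                "rank-deficient design: examples do not vary all three terms"
            )
        fit = lsq_linear(X, y, bounds=([-np.inf, -np.inf, 0.0, 0.0], np.inf))
        coef = ModelCoefficients(
            intercept=float(fit.x[0]),
            w_slide=float(fit.x[1]),
            w_stop=float(fit.x[2]),
            w_bend=float(fit.x[3]),
            se_model=se_model,
            provenance="calibrated on worked examples",
        )
        if choice == prev_choice:
            break
        prev_choice = choice
    fitted = X @ fit.x
    return CalibrationResult(
        coefficients=coef,
        residuals_ln=y - fitted,
        fitted_kd_nM=np.exp(-fitted) * KD_NM_PER_MOLAR,
    )


def worked_examples() -> pd.DataFrame:
    """The published worked-example table (sequences with Kd +/- SE in nM)."""
    return _read_table(_data_path("calibration_examples.tsv"))


@lru_cache(maxsize=1)
def default_calibration() -> CalibrationResult:
    df = worked_examples()
    return calibrate_coefficients(list(zip(df["sequence"], df["kd_nM"])))


def default_coefficients() -> ModelCoefficients:
    """Default coefficient set (calibrated against the worked examples)."""
    return default_calibration().coefficients


def load_coefficients(path: str | Path) -> ModelCoefficients:
    """Load a coefficient config (key-value TSV: ``key value`` rows)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["key", "value"])
    kv = dict(zip(df["key"], df["value"]))
    return ModelCoefficients(
        intercept=float(kv["intercept"]),
        w_slide=float(kv["w_slide"]),
        w_stop=float(kv["w_stop"]),
        w_bend=float(kv["w_bend"]),
        se_model=float(kv.get("se_model", DEFAULT_RELATIVE_SE)),
        se_kind=str(kv.get("se_kind", "relative")),
        provenance=str(kv.get("provenance", str(path))),
    )


def write_estimates_tsv(rows: Iterable[dict], path: str | Path) -> None:
    """Export estimates as TSV (gene, transcript, allele, Kd_nM, SE_nM, site)."""
    pd.DataFrame(list(rows)).to_csv(path, sep="\t", index=False)
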