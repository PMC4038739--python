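"""Synthetic 5C panel generator with ground truth.

Emulates the structure of a region-wide 5C study of a leukemia cell-line
panel: ~40 restriction fragments, interaction frequencies decaying with
genomic distance as a power law, per-primer efficiency biases, per-array
scale factors, multiplicative lognormal measurement noise, and
class-specific planted contact enrichments.  Classes follow the two-level
labelling used throughout the package: MLL status (``fusion`` vs ``wt``)
and fusion subtype (``AF9``, ``ENL``, ...).

The default planted geography mirrors the biology the classifier is meant
to detect: fusion samples gain contacts on pairs involving fragments 26-27
(around HOXA11), wild-type samples gain long-range contacts between the
3' fragments 31-35 and the 5' end plus the neighbour pairs (14,15) and
(32,33), and the two fusion subtypes differ by disjoint contact sets
spread across the whole cluster.

Everything is reproducible bit-for-bit from ``(design, seed)``: one root
generator is split into independent per-sample streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import ContactMatrix, FragmentMap, PanelSample, SamplePanel
from .errors import ValidationError

FUSION_SUBTYPES = ("AF9", "ENL", "AF6", "AFX", "AF4")


@dataclass(frozen=True)
class PlantedEffect:
    """Fold-change applied to one contact pair in samples of one class.

    ``class_label`` may be an MLL status (``fusion``/``wt``) or a subtype;
    a sample matches if either of its labels equals it.
    """

    pair: tuple[int, int]
    fold_change: float
    class_label: str

    def __post_init__(self) -> None:
        i, j = self.pair
        if i == j:
            raise ValidationError("planted pair must join distinct fragments")
        if self.fold_change <= 0:
            raise ValidationError("fold_change must be positive")


def _default_planted(fold: float = 2.5) -> tuple[PlantedEffect, ...]:
    fusion = [(5, 26), (5, 27), (10, 26), (10, 27), (18, 26), (18, 27), (26, 27)]
    wt = [(2, 31), (4, 32), (6, 34), (8, 35), (10, 33), (14, 15), (32, 33)]
    af9 = [(3, 22), (7, 28), (12, 36), (16, 39), (21, 29), (11, 24)]
    enl = [(4, 17), (8, 25), (13, 37), (19, 28), (23, 33), (15, 38)]
    effects = []
    for pairs, label in ((fusion, "fusion"), (wt, "wt"), (af9, "AF9"), (enl, "ENL")):
        effects.extend(PlantedEffect(p, fold, label) for p in pairs)
    return tuple(effects)


@dataclass(frozen=True)
class SimulationDesign:
    """Study-condition bundle for a synthetic panel.

    Defaults reproduce the ``paper_like`` preset: 30 samples (10 AF9 + 10
    ENL fusions, 10 wild-type) over 40 fragments, fold-change 2.5 planted
    signatures, lognormal noise sigma 0.3, primer-efficiency sigma 0.2 and
    per-array scales uniform in [0.5, 2].
    """

    n_fragments: int = 40
    decay_exponent: float = 1.0
    base_if: float = 100.0
    planted_effects: tuple[PlantedEffect, ...] = field(default_factory=_default_planted)
    class_sizes: tuple[tuple[str, int], ...] = (("AF9", 10), ("ENL", 10), ("wt", 10))
    noise_sigma: float = 0.3
    efficiency_sigma: float = 0.2
    array_scale_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0
    sample_prefix: str = ""  # distinguishes ids of independent panels

    def __post_init__(self) -> None:
        if self.n_fragments < 2:
            raise ValidationError("need at least 2 fragments")
        if self.decay_exponent <= 0:
            raise ValidationError("decay exponent must be positive")
        if self.base_if <= 0:
            raise ValidationError("base_if must be positive")
        for e in self.planted_effects:
            for k in e.pair:
                if not 1 <= k <= self.n_fragments:
                    raise ValidationError(
                        f"planted fragment {k} outside 1..{self.n_fragments}"
                    )
        for label, count in self.class_sizes:
            if count < 1:
                raise ValidationError(f"class {label!r} has nonpositive size")
        if self.noise_sigma < 0 or self.efficiency_sigma < 0:
            raise ValidationError("noise sigmas must be nonnegative")
        lo, hi = self.array_scale_range
        if not 0 < lo <= hi:
            raise ValidationError("bad array_scale_range")


def paper_like_design(
    seed: int = 0, fold_change: float = 2.5, noise_sigma: float = 0.3
) -> SimulationDesign:
    """The default preset: 20 fusion (10 AF9 + 10 ENL) vs 10 wt, 40 fragments."""
    return SimulationDesign(
        planted_effects=_default_planted(fold_change),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def null_design(seed: int = 0, noise_sigma: float = 0.3) -> SimulationDesign:
    """Same panel shape but no planted effects: labels carry no signal."""
    return SimulationDesign(planted_effects=(), noise_sigma=noise_sigma, seed=seed)


@dataclass
class GroundTruth:
    sample_id: str
    true_if: np.ndarray  # noise-free expected matrix incl. planted effects
    efficiencies: np.ndarray
    array_scale: float
    mll_status: str
    subtype: str


def baseline_expected(
    n_fragments: int, decay_exponent: float, base_if: float
) -> ContactMatrix:
    """Distance-decay expectation ``base_if * |i-j|^-alpha``; the diagonal
    (self-ligation) is left unmeasured."""
    if n_fragments < 2:
        raise ValidationError("need at least 2 fragments")
    if decay_exponent <= 0:
        raise ValidationError("decay exponent must be positive")
    if base_if <= 0:
        raise ValidationError("base_if must be positive")
    idx = np.arange(n_fragments)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        values = base_if * dist ** (-decay_exponent)
    np.fill_diagonal(values, np.nan)
    return ContactMatrix.from_dense(values)


def _status_of(subtype: str) -> str:
    return "fusion" if subtype in FUSION_SUBTYPES else "wt"


def true_matrix(design: SimulationDesign, subtype: str) -> np.ndarray:
    """Noise-free expected IFs for one class: baseline times planted folds."""
    base = baseline_expected(
        design.n_fragments, design.decay_exponent, design.base_if
    ).values.copy()
    status = _status_of(subtype)
    for eff in design.planted_effects:
        if eff.class_label in (subtype, status):
            i, j = eff.pair[0] - 1, eff.pair[1] - 1
            base[i, j] *= eff.fold_change
            base[j, i] *= eff.fold_change
    return base


def simulate_sample(
    design: SimulationDesign,
    class_label: str,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> tuple[ContactMatrix, GroundTruth]:
    """Draw one raw matrix: true IF x e_i e_j x array scale x lognormal noise.

    The noise term is symmetric (each contact is a single measurement), as
    are the efficiency products, so the raw matrix stays a valid contact map.
    """
    n = design.n_fragments
    true = true_matrix(design, class_label)
    eff = np.exp(rng.normal(0.0, design.efficiency_sigma, size=n))
    scale = float(rng.uniform(*design.array_scale_range))
    noise = rng.normal(0.0, design.noise_sigma, size=(n, n))
    noise = np.triu(noise) + np.triu(noise, k=1).T  # mirror upper triangle
    raw_values = true * np.outer(eff, eff) * scale * np.exp(noise)
    raw = ContactMatrix.from_dense(raw_values)
    gt = GroundTruth(
        sample_id=sample_id,
        true_if=true,
        efficiencies=eff,
        array_scale=scale,
        mll_status=_status_of(class_label),
        subtype=class_label if class_label in FUSION_SUBTYPES else "none",
    )
    return raw, gt


# wt samples cycle through leukemia types; the wild-type arm of the study
# mixed AML, ALL and embryonal-carcinoma lines
_WT_TYPES = ("AML", "ALL", "EC")
_SUBTYPE_TYPES = {"AF9": "AML", "ENL": "ALL", "AF4": "ALL", "AF6": "AML", "AFX": "ALL"}


def simulate_panel(
    design: SimulationDesign,
) -> tuple[SamplePanel, list[GroundTruth]]:
    """Generate a labelled panel respecting ``design.class_sizes``.

    Per-sample random streams are split deterministically from the root
    seed, so inserting or removing a class does not perturb other samples'
    draws beyond their position in the declaration order.
    """
    root = np.random.default_rng(design.seed)
    n_samples = sum(c for _, c in design.class_sizes)
    streams = root.spawn(n_samples)
    fmap = FragmentMap.uniform(design.n_fragments)
    samples: list[PanelSample] = []
    truths: list[GroundTruth] = []
    k = 0
    wt_counter = 0
    for label, count in design.class_sizes:
        for r in range(count):
            sid = f"{design.sample_prefix}{label}_{r + 1:02d}"
            raw, gt = simulate_sample(design, label, streams[k], sample_id=sid)
            k += 1
            raw.fragment_map = fmap
            if label in FUSION_SUBTYPES:
                ltype = _SUBTYPE_TYPES[label]
                subtype = label
                status = "fusion"
            else:
                ltype = _WT_TYPES[wt_counter % len(_WT_TYPES)]
                wt_counter += 1
                subtype = "none"
                status = "wt"
            samples.append(
                PanelSample(
                    sample_id=sid,
                    matrix=raw,
                    mll_status=status,
                    subtype=subtype,
                    leukemia_type=ltype,
                )
            )
            truths.append(gt)
    return SamplePanel(samples, fmap), truths
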