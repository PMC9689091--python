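"""Synthetic LC-MS lipidomics cohorts for the T2DM progression analysis.

Real cohorts for this problem are private, so every downstream stage of the
pipeline is exercised on generated data with the same statistical structure:
positive, right-skewed (log-normal) intensities; a per-sample multiplicative
dilution factor; and a small set of *planted* metabolites whose mean
log-intensity shifts between the two stages of a pairwise comparison.  The
ground truth (which features were planted where, and each sample's dilution)
is returned alongside the table, never written into it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .table import FeatureTable

__all__ = [
    "STAGES",
    "COMPARISON_PAIRS",
    "PROGRESSION_BIOMARKERS",
    "ConfigurationError",
    "SyntheticSpec",
    "GroundTruth",
    "generate_dataset",
    "default_planted_map",
    "write_ground_truth",
    "read_ground_truth",
]

#: Disease-progression stages, in order: healthy controls, prediabetes,
#: type 2 diabetes mellitus, diabetic nephropathy.
STAGES: tuple[str, ...] = ("Control", "Prediabetes", "T2DM", "DN")

#: The five pairwise stage comparisons the analysis runs, in canonical order.
COMPARISON_PAIRS: tuple[tuple[str, str], ...] = (
    ("Control", "Prediabetes"),
    ("Control", "T2DM"),
    ("Prediabetes", "T2DM"),
    ("Control", "DN"),
    ("T2DM", "DN"),
)

#: Metabolites planted, by default, in more than one comparison -- the pattern
#: a cross-comparison progression biomarker shows.  Values are the comparisons
#: (by pair) each name discriminates.
PROGRESSION_BIOMARKERS: dict[str, tuple[tuple[str, str], ...]] = {
    "Cer(d18:1/24:1) i2": (
        ("Control", "Prediabetes"),
        ("Control", "DN"),
        ("T2DM", "DN"),
    ),
    "PC(20:3-OH/P-18:1)": (("Control", "Prediabetes"), ("Prediabetes", "T2DM")),
    "Ganoderic acid C2": (("Control", "T2DM"), ("Prediabetes", "T2DM")),
    "TG(16:0/17:1/18:1)": (("Control", "DN"), ("T2DM", "DN")),
    "GPEtn(18:0/20:4)": (("Control", "DN"), ("T2DM", "DN")),
}


class ConfigurationError(ValueError):
    """Raised when a spec or configuration object is internally inconsistent."""


def comparison_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}-{pair[1]}"


def default_planted_map(
    effect: float = 0.6, extras_per_pair: int = 2
) -> dict[tuple[str, str], dict[int, float]]:
    """The default planting layout.

    Features 0-4 carry the five cross-comparison biomarker names and are
    planted in the comparisons listed in :data:`PROGRESSION_BIOMARKERS`;
    each comparison additionally gets ``extras_per_pair`` private features.
    ``effect`` is the mean log-intensity shift (natural log units).
    """
    planted: dict[tuple[str, str], dict[int, float]] = {p: {} for p in COMPARISON_PAIRS}
    for idx, pairs in enumerate(PROGRESSION_BIOMARKERS.values()):
        for pair in pairs:
            planted[pair][idx] = effect
    nxt = len(PROGRESSION_BIOMARKERS)
    for pair in COMPARISON_PAIRS:
        for _ in range(extras_per_pair):
            planted[pair][nxt] = effect
            nxt += 1
    return planted


@dataclass
class SyntheticSpec:
    """Parameters of a generated cohort.

    Parameters
    ----------
    n_per_group : int
        Samples per stage (default 20, i.e. 80 samples over four stages).
    n_features : int
        Number of metabolite features (default 717).
    stages : sequence of str
        Ordered stage labels; pairs in ``planted_map`` must use these.
    planted_map : mapping (stage, stage) -> mapping feature index -> effect
        Discriminative features per comparison.  Effects are mean shifts of
        log-intensity, in natural-log units; the later stage of the pair is
        shifted upward.  ``None`` selects :func:`default_planted_map`.
    noise_sd : float
        Within-group standard deviation of log-intensity (biological plus
        technical scatter).  Default 0.3, roughly a 30% coefficient of
        variation, typical of untargeted lipidomics cohorts.
    dilution_range : (float, float)
        Bounds of the uniform per-sample dilution factor.
    feature_names : sequence of str, optional
        Explicit metabolite names; ``None`` generates lipid-style names, with
        the five :data:`PROGRESSION_BIOMARKERS` names injected at the planted
        indices when the default map is in use.
    seed : int
        RNG seed; a fixed seed gives a bit-identical dataset.
    """

    n_per_group: int = 20
    n_features: int = 717
    stages: Sequence[str] = STAGES
    planted_map: Mapping[tuple[str, str], Mapping[int, float]] | None = None
    noise_sd: float = 0.3
    dilution_range: tuple[float, float] = (0.5, 2.0)
    feature_names: Sequence[str] | None = None
    seed: int = 0

    def resolved_planted_map(self) -> dict[tuple[str, str], dict[int, float]]:
        if self.planted_map is None:
            return default_planted_map()
        return {tuple(k): dict(v) for k, v in self.planted_map.items()}

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if len(set(self.stages)) != len(self.stages) or len(self.stages) < 2:
            raise ConfigurationError("stages must be >= 2 distinct labels")
        lo, hi = self.dilution_range
        if not (0 < lo <= hi):
            raise ConfigurationError("dilution bounds must be strictly positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        for pair, feats in self.resolved_planted_map().items():
            a, b = pair
            if a not in self.stages or b not in self.stages:
                raise ConfigurationError(f"planted pair {pair} uses unknown stage")
            for idx in feats:
                if not 0 <= idx < self.n_features:
                    raise ConfigurationError(
                        f"planted feature index {idx} out of range "
                        f"(n_features={self.n_features})"
                    )
        if self.feature_names is not None and len(self.feature_names) != self.n_features:
            raise ConfigurationError("feature_names length must equal n_features")


@dataclass
class GroundTruth:
    """What the generator actually did: kept separate from the data file."""

    planted: dict[str, dict[str, float]]  # comparison name -> feature name -> effect
    dilutions: pd.Series = field(repr=False)  # per sample id

    def planted_features(self, comparison: str | None = None) -> set[str]:
        if comparison is not None:
            return set(self.planted.get(comparison, {}))
        out: set[str] = set()
        for feats in self.planted.values():
            out |= set(feats)
        return out


# -- name generation -------------------------------------------------------

_LIPID_CLASSES = (
    "TG", "DG", "MG", "PC", "PE", "PA", "PS", "PG", "SM", "Cer", "CerP",
    "GPCho", "GPEtn", "GPSer", "CE", "LPC", "MGDG", "DGDG",
)
_CHAINS_PER_CLASS = {
    "TG": 3, "DG": 3, "MG": 3, "MGDG": 2, "DGDG": 2, "CE": 1, "LPC": 1,
}


def _acyl(rng: np.random.Generator) -> str:
    return f"{rng.integers(12, 25)}:{rng.integers(0, 7)}"


def _lipid_name(rng: np.random.Generator) -> str:
    cls = _LIPID_CLASSES[rng.integers(0, len(_LIPID_CLASSES))]
    n_chains = _CHAINS_PER_CLASS.get(cls, 2)
    chains = [_acyl(rng) for _ in range(n_chains)]
    if cls in ("SM", "Cer", "CerP"):
        chains[0] = "d" + chains[0]
    return f"{cls}({'/'.join(chains)})"


def _generate_names(
    rng: np.random.Generator,
    n: int,
    inject_biomarkers: bool,
) -> list[str]:
    seen: set[str] = set()
    names: list[str] = []
    if inject_biomarkers:
        names = list(PROGRESSION_BIOMARKERS)[: min(n, len(PROGRESSION_BIOMARKERS))]
        seen = set(names)
    while len(names) < n:
        name = _lipid_name(rng)
        if name in seen:  # isomer tag, like the annotation software emits
            for tag in range(2, 10):
                cand = f"{name} i{tag}"
                if cand not in seen:
                    name = cand
                    break
            else:
                continue
        seen.add(name)
        names.append(name)
    return names


# -- generation ------------------------------------------------------------

def _stage_deltas(spec: SyntheticSpec) -> np.ndarray:
    """Per-(stage, feature) mean log shift implied by the planted map.

    Overlapping plantings (one feature discriminating several comparisons)
    are reconciled by propagating shifts along the stage order: for pair
    (a, b) with effect e, stage b's shift becomes max(current, shift(a) + e).
    """
    stage_idx = {s: i for i, s in enumerate(spec.stages)}
    delta = np.zeros((len(spec.stages), spec.n_features))
    pairs = sorted(
        spec.resolved_planted_map().items(),
        key=lambda kv: (stage_idx[kv[0][1]], stage_idx[kv[0][0]]),
    )
    for (a, b), feats in pairs:
        for f, effect in feats.items():
            delta[stage_idx[b], f] = max(
                delta[stage_idx[b], f], delta[stage_idx[a], f] + effect
            )
    return delta


def generate_dataset(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw one cohort from ``spec``.

    Returns the feature table (intensities already multiplied by each
    sample's dilution factor) and the ground truth needed by tests:
    planted feature names per comparison and the drawn dilutions.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    planted = spec.resolved_planted_map()

    if spec.feature_names is not None:
        names = list(spec.feature_names)
    else:
        names = _generate_names(rng, spec.n_features, spec.planted_map is None)

    n_stages = len(spec.stages)
    n = spec.n_per_group * n_stages
    stage_labels = np.repeat(list(spec.stages), spec.n_per_group)

    # log-normal intensities: per-feature baseline shared across stages,
    # plus planted stage shifts, plus within-group scatter
    base = rng.normal(12.0, 1.5, size=spec.n_features)
    delta = _stage_deltas(spec)
    stage_of = {s: i for i, s in enumerate(spec.stages)}
    shifts = delta[[stage_of[s] for s in stage_labels], :]
    log_i = base[None, :] + shifts + rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))

    lo, hi = spec.dilution_range
    dilutions = rng.uniform(lo, hi, size=n)
    intensities = np.exp(log_i) * dilutions[:, None]

    width = len(str(n))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    frame = pd.DataFrame(intensities, index=pd.Index(sample_ids, name="sample_id"),
                         columns=names)
    stages = pd.Series(stage_labels, index=frame.index, name="stage")

    truth = GroundTruth(
        planted={
            comparison_name(pair): {names[f]: e for f, e in feats.items()}
            for pair, feats in planted.items()
            if feats
        },
        dilutions=pd.Series(dilutions, index=frame.index, name="dilution"),
    )
    return FeatureTable(frame, stages), truth


# -- ground-truth sidecar ---------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "planted": truth.planted,
        "dilutions": {k: float(v) for k, v in truth.dilutions.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    dil = pd.Series(payload["dilutions"], name="dilution")
    dil.index.name = "sample_id"
    return GroundTruth(planted=payload["planted"], dilutions=dil)
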