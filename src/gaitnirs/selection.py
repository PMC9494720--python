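"""Multi-stage statistical feature selection over subband slope matrices.

For one class of one dimension (say the low-speed class, whose
constituent states are SP-LD and MP-LD), each subject's per-state
6 x 22 slope matrices are reduced to a chain of matrices:

* M1 — elementwise mean over the constituent states;
* M2 — |coefficient of variation| over the constituent states;
* M3 — indicator of the bottom 50 % of M2 (cells stable across the
  constituent states);
* M4 / M5 — indicators of the top / bottom 20 % of M1 (cells with
  clear activation / inhibition);
* M6 = M3 AND M4, M7 = M3 AND M5 — *key channels*;
* M8 / M9 — per-region counts of key channels (6 bands x 22 regions).

Across the training cohort, a (band, region, polarity) cell selected in
at least 60 % of subjects becomes a feature region; its key-channel
count is the modal per-subject count.  Feature regions in adjacent
bands of the same half of the spectrum (pd1–pd3: 0–0.09 Hz, pd4–pd6:
0.09–0.18 Hz) merge into a single feature vector.  Finally one-way
ANOVA between every pair of target classes, on per-subject feature
values, discards features that discriminate no pair at the 0.05 level.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import N_CHANNELS, ValidationError
from .regions import REGION_MAP
from .states import constituent_states, dimension_classes

#: fraction of cells kept by the CV stability mask (M3)
CV_KEEP = 0.5

#: fraction of cells flagged as activated / inhibited (M4, M5)
EXTREME_FRAC = 0.2

#: cross-subject frequency threshold for feature regions
FREQ_THRESHOLD = 0.6

#: ANOVA significance level
ALPHA = 0.05

#: subbands below / above the 0.09 Hz boundary
LOW_PART = frozenset({1, 2, 3})
HIGH_PART = frozenset({4, 5, 6})


@dataclass
class SelectionMatrices:
    """The per-subject matrix chain M1 … M9 for one class group."""

    M1: np.ndarray
    M2: np.ndarray
    M3: np.ndarray
    M4: np.ndarray
    M5: np.ndarray
    M6: np.ndarray
    M7: np.ndarray
    M8: np.ndarray
    M9: np.ndarray


@dataclass(frozen=True)
class FeatureSpec:
    """A selected feature vector in region / subband notation.

    ``bands`` lists the constituent subbands (all within one spectral
    part) and ``key_counts`` the per-band number of key channels, so a
    merged feature prints exactly as e.g. ``"Re4: pd1(1) + pd2(1)"``.
    """

    region: int
    polarity: str  # "top" (activation) or "bottom" (inhibition)
    bands: tuple[int, ...]
    key_counts: tuple[int, ...]
    signal_kind: str

    def __post_init__(self) -> None:
        if self.polarity not in ("top", "bottom"):
            raise ValidationError("polarity must be 'top' or 'bottom'")
        if len(self.bands) != len(self.key_counts) or not self.bands:
            raise ValidationError("bands and key_counts must align and be non-empty")
        part = LOW_PART if self.bands[0] in LOW_PART else HIGH_PART
        if not set(self.bands) <= part:
            raise ValidationError(
                f"bands {self.bands} cross the 0.09 Hz boundary (pd3|pd4)"
            )
        if any(not 1 <= k <= 3 for k in self.key_counts):
            raise ValidationError("key counts must be in 1..3 (regions have 3 channels)")

    @property
    def notation(self) -> str:
        terms = " + ".join(f"pd{b}({k})" for b, k in zip(self.bands, self.key_counts))
        return f"Re{self.region}: {terms}"

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "polarity": self.polarity,
            "bands": list(self.bands),
            "key_counts": list(self.key_counts),
            "signal_kind": self.signal_kind,
            "notation": self.notation,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSpec":
        return cls(
            region=int(d["region"]),
            polarity=str(d["polarity"]),
            bands=tuple(int(b) for b in d["bands"]),
            key_counts=tuple(int(k) for k in d["key_counts"]),
            signal_kind=str(d["signal_kind"]),
        )


def _rank_mask(flat: np.ndarray, n_keep: int, largest: bool) -> np.ndarray:
    """Indicator of the ``n_keep`` largest/smallest entries.

    Ties are broken by ascending flat (band-major, i.e. (band, channel))
    index so the mask is deterministic.
    """
    order = np.argsort(-flat if largest else flat, kind="stable")
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:n_keep]] = True
    return mask


def build_selection_matrices(matrices: Sequence[np.ndarray]) -> SelectionMatrices:
    """Compute M1 … M9 from one subject's constituent-state matrices.

    Requires at least two 6 x 22 matrices (the CV needs replication).
    A cell whose mean is exactly zero has undefined CV and is assigned
    +inf so the stability mask can never select it.
    """
    mats = np.asarray([np.asarray(m, dtype=float) for m in matrices])
    if mats.ndim != 3 or mats.shape[0] < 2:
        raise ValidationError("need at least two constituent-state matrices")
    if mats.shape[1:] != (6, N_CHANNELS):
        raise ValidationError(f"matrices must be 6 x {N_CHANNELS}, got {mats.shape[1:]}")

    M1 = mats.mean(axis=0)
    sd = mats.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        M2 = np.abs(sd / M1)
    M2[M1 == 0] = np.inf

    n_cells = M1.size
    M3 = _rank_mask(M2.ravel(), math.floor(CV_KEEP * n_cells), largest=False)
    M4 = _rank_mask(M1.ravel(), math.floor(EXTREME_FRAC * n_cells), largest=True)
    M5 = _rank_mask(M1.ravel(), math.floor(EXTREME_FRAC * n_cells), largest=False)
    M3, M4, M5 = (m.reshape(M1.shape) for m in (M3, M4, M5))
    M6 = M3 & M4
    M7 = M3 & M5
    M8, M9 = regionize(M6, M7)
    return SelectionMatrices(M1, M2, M3, M4, M5, M6, M7, M8, M9)


def regionize(
    M6: np.ndarray, M7: np.ndarray, region_map: Mapping[int, tuple] = REGION_MAP
) -> tuple[np.ndarray, np.ndarray]:
    """Count key channels per (band, region): the quantized M8 / M9."""
    M6 = np.asarray(M6, dtype=bool)
    M7 = np.asarray(M7, dtype=bool)
    if M6.shape != M7.shape or M6.shape[1] != N_CHANNELS:
        raise ValidationError("masks must be (n_bands, 22) and congruent")
    n_regions = len(region_map)
    M8 = np.zeros((M6.shape[0], n_regions), dtype=int)
    M9 = np.zeros_like(M8)
    for j, region in enumerate(sorted(region_map)):
        cols = [c - 1 for c in region_map[region]]
        M8[:, j] = M6[:, cols].sum(axis=1)
        M9[:, j] = M7[:, cols].sum(axis=1)
    return M8, M9


def _modal_count(counts: Iterable[int], rule: str) -> int:
    nonzero = [c for c in counts if c > 0]
    if rule == "max":
        return max(nonzero)
    # mode; ties resolved toward the smaller count
    freq = Counter(nonzero)
    return min(sorted(freq), key=lambda c: (-freq[c], c))


def cohort_frequency_selection(
    per_subject: Sequence[tuple[np.ndarray, np.ndarray]],
    signal_kind: str,
    threshold: float = FREQ_THRESHOLD,
    key_count_rule: str = "mode",
) -> list[FeatureSpec]:
    """Keep (band, region, polarity) cells recurring across subjects.

    A cell is a feature region when at least ``ceil(threshold * n)`` of
    the ``n`` subjects have a nonzero key-channel count there (>= 12 of
    20 at the default 60 %).  Its key-channel count is the most frequent
    nonzero per-subject count among the selecting subjects (ties toward
    the smaller count; ``key_count_rule="max"`` takes the maximum
    instead).
    """
    if not per_subject:
        raise ValidationError("no subject matrices given")
    if key_count_rule not in ("mode", "max"):
        raise ValidationError("key_count_rule must be 'mode' or 'max'")
    n = len(per_subject)
    required = math.ceil(threshold * n)
    specs: list[FeatureSpec] = []
    for polarity, which in (("top", 0), ("bottom", 1)):
        counts = np.asarray([ms[which] for ms in per_subject])  # (n, bands, regions)
        for band in range(counts.shape[1]):
            for j in range(counts.shape[2]):
                cell = counts[:, band, j]
                if int((cell > 0).sum()) >= required:
                    kc = _modal_count(cell.tolist(), key_count_rule)
                    specs.append(
                        FeatureSpec(
                            region=j + 1,
                            polarity=polarity,
                            bands=(band + 1,),
                            key_counts=(kc,),
                            signal_kind=signal_kind,
                        )
                    )
    return specs


def merge_contiguous_bands(specs: Sequence[FeatureSpec]) -> list[FeatureSpec]:
    """Merge feature regions in adjacent bands of the same spectral part.

    Within each (region, polarity, signal kind), runs of consecutive
    subbands combine into a single feature vector; runs never cross the
    0.09 Hz boundary between pd3 and pd4.
    """
    groups: dict[tuple, dict[int, int]] = {}
    for s in specs:
        key = (s.signal_kind, s.region, s.polarity)
        bands = groups.setdefault(key, {})
        for b, k in zip(s.bands, s.key_counts):
            # the same cell may arrive from several class groups; keep the
            # larger key-channel count deterministically
            bands[b] = max(bands.get(b, 0), k)
    merged: list[FeatureSpec] = []
    for (kind, region, polarity), band_counts in sorted(groups.items()):
        run: list[int] = []
        for b in sorted(band_counts) + [None]:  # type: ignore[list-item]
            joinable = (
                run
                and b is not None
                and b == run[-1] + 1
                and (b in LOW_PART) == (run[-1] in LOW_PART)
            )
            if joinable:
                run.append(b)
                continue
            if run:
                merged.append(
                    FeatureSpec(
                        region=region,
                        polarity=polarity,
                        bands=tuple(run),
                        key_counts=tuple(band_counts[x] for x in run),
                        signal_kind=kind,
                    )
                )
            run = [b] if b is not None else []
    return merged


def extract_feature_value(
    matrix: np.ndarray,
    spec: FeatureSpec,
    region_map: Mapping[int, tuple] = REGION_MAP,
    mode: str = "mean",
) -> float | np.ndarray:
    """Evaluate one feature spec on one 6 x 22 matrix.

    Per constituent band, take the mean of the ``key_count`` largest
    (polarity ``"top"``) or smallest (``"bottom"``) values among the
    region's three channels; a merged spec's scalar is the mean over its
    bands (``mode="concat"`` returns the per-band values instead).
    """
    matrix = np.asarray(matrix, dtype=float)
    cols = [c - 1 for c in region_map[spec.region]]
    per_band = []
    for band, kc in zip(spec.bands, spec.key_counts):
        vals = np.sort(matrix[band - 1, cols])
        chosen = vals[-kc:] if spec.polarity == "top" else vals[:kc]
        per_band.append(chosen.mean())
    per_band = np.asarray(per_band)
    if mode == "concat":
        return per_band
    return float(per_band.mean())


def anova_filter(
    values_by_class: Mapping[str, Mapping[str, Sequence[float]]],
    alpha: float = ALPHA,
) -> tuple[list[str], dict[str, dict[str, float]]]:
    """Keep features discriminating at least one pair of classes.

    ``values_by_class[feature_id][class_label]`` holds the per-subject
    scalars of one feature in one class.  For every pair of classes a
    one-way ANOVA (equivalently a squared two-sample t) is run; the
    feature is retained iff any pairwise p-value is below ``alpha``.
    Degenerate pairs (zero variance, equal means) count as p = 1.

    Returns the retained feature ids and all pairwise p-values.
    """
    retained: list[str] = []
    pvalues: dict[str, dict[str, float]] = {}
    for feat_id, groups in values_by_class.items():
        labels = sorted(groups)
        pv: dict[str, float] = {}
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                ga, gb = np.asarray(groups[a], float), np.asarray(groups[b], float)
                if min(ga.size, gb.size) < 2:
                    raise ValidationError("each class needs at least two subjects")
                with np.errstate(invalid="ignore", divide="ignore"):
                    res = stats.f_oneway(ga, gb)
                p = float(res.pvalue)
                pv[f"{a}|{b}"] = 1.0 if math.isnan(p) else p
        pvalues[feat_id] = pv
        if any(p < alpha for p in pv.values()):
            retained.append(feat_id)
    return retained, pvalues


# ---------------------------------------------------------------------------
# cohort-level driver


@dataclass
class SelectionResult:
    """Outcome of feature selection for one classification dimension."""

    dimension: str
    specs: list[FeatureSpec]
    candidate_specs: list[FeatureSpec]
    pvalues: dict[str, dict[str, float]]
    class_means: dict = field(default_factory=dict)


FeatureMatrixTable = Mapping[tuple[str, str, str], np.ndarray]
"""Slope matrices keyed by (subject_id, state label, signal_kind)."""


def class_mean_matrix(
    featmats: FeatureMatrixTable,
    subject: str,
    class_label: str,
    dimension: str,
    signal_kind: str,
) -> np.ndarray:
    """One subject's M1 for one class: mean over constituent states."""
    mats = [
        featmats[(subject, s.label, signal_kind)]
        for s in constituent_states(class_label, dimension)
    ]
    return np.mean(mats, axis=0)


def select_features(
    featmats: FeatureMatrixTable,
    subjects: Sequence[str],
    dimension: str,
    signal_kinds: Sequence[str] = ("totalHb", "oxy_minus_deoxy"),
    threshold: float = FREQ_THRESHOLD,
    alpha: float = ALPHA,
    key_count_rule: str = "mode",
) -> SelectionResult:
    """Run the full selection cascade for one dimension on a cohort.

    For every class of the dimension with at least two constituent
    states, each training subject's matrices pass through the M1–M9
    chain; cross-subject frequency statistics then yield candidate
    feature regions, which are merged across adjacent bands and finally
    filtered by pairwise ANOVA over the dimension's classes.  Classes
    with a single constituent state (e.g. the high-speed class, whose
    only state is MP-HD) cannot support a CV and contribute no
    candidates, but they do enter the ANOVA as a comparison class.
    """
    classes = dimension_classes(dimension)
    candidates: list[FeatureSpec] = []
    for kind in signal_kinds:
        for cls in classes:
            if len(constituent_states(cls, dimension)) < 2:
                continue
            per_subject = []
            for subject in subjects:
                mats = [
                    featmats[(subject, s.label, kind)]
                    for s in constituent_states(cls, dimension)
                ]
                sel = build_selection_matrices(mats)
                per_subject.append((sel.M8, sel.M9))
            candidates.extend(
                cohort_frequency_selection(per_subject, kind, threshold, key_count_rule)
            )
    # merge adjacent bands, then drop duplicates arising from different classes
    merged = merge_contiguous_bands(candidates)
    merged = sorted(set(merged), key=lambda s: (s.signal_kind, s.region, s.bands, s.polarity))

    values_by_class: dict[str, dict[str, list[float]]] = {}
    spec_by_id: dict[str, FeatureSpec] = {}
    for spec in merged:
        groups: dict[str, list[float]] = {}
        for cls in classes:
            groups[cls] = [
                extract_feature_value(
                    class_mean_matrix(featmats, subj, cls, dimension, spec.signal_kind),
                    spec,
                )
                for subj in subjects
            ]
        fid = f"{spec.notation} [{spec.polarity}, {spec.signal_kind}]"
        values_by_class[fid] = groups
        spec_by_id[fid] = spec

    retained_ids, pvalues = anova_filter(values_by_class, alpha)
    retained = [spec_by_id[i] for i in retained_ids]
    class_means = {
        fid: {c: float(np.mean(v)) for c, v in groups.items()}
        for fid, groups in values_by_class.items()
    }
    return SelectionResult(
        dimension=dimension,
        specs=retained,
        candidate_specs=merged,
        pvalues=pvalues,
        class_means=class_means,
    )
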