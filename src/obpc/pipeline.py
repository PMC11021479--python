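"""Calcium-response analysis for odor-evoked ΔF/F amplitude tensors.

Inputs are ROI × stimulus × trial response amplitudes (mean ΔF/F in a fixed
window after odor onset) together with blank (no-odorant) trials.  The
pipeline covers:

* significance classification against a per-ROI 3-SD blank-trial threshold,
  with enhanced / suppressed / nonresponsive labels;
* ROI filtering (keep ROIs with at least one significant response) and
  polarity classes (pure-enhanced / pure-suppressed / mixed / silent);
* tuning breadth (effective odorant counts), population and lifetime
  sparseness, ranked-normalized tuning curves and distances from the mean
  curve;
* representational similarity (Pearson correlation between population
  vectors), trial-to-trial reliability, hierarchical ordering of correlation
  matrices, and mixture-overlap group comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "Stimulus",
    "StimulusPanel",
    "ResponseTensor",
    "ClassifiedResponses",
    "SimilarityMatrix",
    "SparsenessReport",
    "OverlapComparison",
    "N_COMPONENTS",
    "classify_responses",
    "filter_rois",
    "polarity_class",
    "polarity_fractions",
    "effective_odorant_count",
    "population_sparseness",
    "lifetime_sparseness",
    "sparseness_report",
    "ranked_tuning_curve",
    "curve_distance",
    "representational_similarity",
    "within_stimulus_reliability",
    "hierarchical_order",
    "mixture_overlap",
    "overlap_group_comparison",
]

N_COMPONENTS = 16  # size of the monomolecular odorant alphabet

ENHANCED, NONRESPONSIVE, SUPPRESSED = 1, 0, -1
_LABEL_NAMES = {ENHANCED: "enhanced", NONRESPONSIVE: "nonresponsive",
                SUPPRESSED: "suppressed"}


# ---------------------------------------------------------------------------
# Stimuli and response tensors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stimulus:
    """One stimulus: a monomolecular odorant, a mixture, or a concentration step."""

    id: str
    kind: str  # "odorant" | "mixture" | "concentration_step"
    components: frozenset = frozenset()
    concentration_level: int | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("odorant", "mixture", "concentration_step"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        comps = frozenset(self.components)
        if not comps <= set(range(N_COMPONENTS)):
            raise ValueError(f"components must be a subset of 0..{N_COMPONENTS - 1}")
        object.__setattr__(self, "components", comps)

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class StimulusPanel:
    stimuli: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "stimuli", tuple(self.stimuli))
        ids = [s.id for s in self.stimuli]
        if len(set(ids)) != len(ids):
            raise ValueError("stimulus ids must be unique")

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    @property
    def ids(self) -> list:
        return [s.id for s in self.stimuli]

    @property
    def sizes(self) -> np.ndarray:
        return np.array([s.n_components for s in self.stimuli])

    def size_histogram(self) -> dict:
        sizes, counts = np.unique(self.sizes, return_counts=True)
        return dict(zip(sizes.tolist(), counts.tolist()))

    def indices_of_size(self, *sizes: int) -> np.ndarray:
        return np.flatnonzero(np.isin(self.sizes, sizes))


@dataclass(frozen=True)
class ResponseTensor:
    """ΔF/F response amplitudes: ROI × stimulus × trial, plus blank trials."""

    amplitudes: np.ndarray
    blank_amplitudes: np.ndarray
    panel: StimulusPanel
    roi_ids: tuple = ()
    population_label: str = "OSN"

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=float)
        blank = np.asarray(self.blank_amplitudes, dtype=float)
        if amp.ndim != 3:
            raise ValueError("amplitudes must be ROI × stimulus × trial")
        if amp.shape[1] != len(self.panel):
            raise ValueError("stimulus axis does not match the panel")
        if blank.ndim != 2 or blank.shape[0] != amp.shape[0]:
            raise ValueError("blank_amplitudes must be ROI × blank-trial")
        if blank.shape[1] < 1:
            raise ValueError("at least one blank trial per ROI is required")
        if not (np.isfinite(amp).all() and np.isfinite(blank).all()):
            raise ValueError("amplitudes must be finite (no missing values)")
        if self.population_label not in ("OSN", "bouton"):
            raise ValueError("population_label must be 'OSN' or 'bouton'")
        roi_ids = tuple(self.roi_ids) or tuple(f"roi{i:04d}" for i in range(amp.shape[0]))
        if len(roi_ids) != amp.shape[0]:
            raise ValueError("roi_ids length must match the ROI axis")
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "blank_amplitudes", blank)
        object.__setattr__(self, "roi_ids", roi_ids)

    @property
    def n_rois(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def n_trials(self) -> int:
        return self.amplitudes.shape[2]

    def trial_mean(self) -> np.ndarray:
        return self.amplitudes.mean(axis=2)


# ---------------------------------------------------------------------------
# Significance classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifiedResponses:
    """Per ROI-stimulus labels with the blank-derived thresholds used.

    ``labels`` codes: 1 enhanced, 0 nonresponsive, -1 suppressed.  The label
    is enhanced iff the across-trial mean exceeds the ROI's high threshold
    (strictly), suppressed iff it falls below the low threshold.
    """

    labels: np.ndarray
    thresholds: np.ndarray  # n_rois × 2 (low, high)
    trial_mean: np.ndarray
    n_sd: float
    pooled_fallback_rois: tuple = ()

    def label_names(self) -> np.ndarray:
        return np.vectorize(_LABEL_NAMES.get)(self.labels)

    @property
    def n_rois(self) -> int:
        return self.labels.shape[0]


def classify_responses(tensor: ResponseTensor, n_sd: float = 3.0,
                       threshold_mode: str = "per_roi") -> ClassifiedResponses:
    """Label each ROI-stimulus pair by a blank-trial noise criterion.

    Thresholds are ``blank mean ± n_sd × blank SD`` computed per ROI from that
    ROI's own blank trials (``threshold_mode='per_roi'``, the default, since
    noise levels differ across ROIs) or from all blanks pooled after removing
    per-ROI means (``'pooled'``).  ROIs whose blank variance is zero (or
    inestimable) fall back to the pooled SD and are flagged.
    """
    if n_sd < 0:
        raise ValueError("n_sd must be >= 0")
    if threshold_mode not in ("per_roi", "pooled"):
        raise ValueError("threshold_mode must be 'per_roi' or 'pooled'")
    blank = tensor.blank_amplitudes
    blank_mean = blank.mean(axis=1)
    centered = blank - blank_mean[:, None]
    pooled_sd = float(centered.std(ddof=1)) if blank.size > 1 else 0.0
    if blank.shape[1] >= 2:
        roi_sd = blank.std(axis=1, ddof=1)
    else:
        roi_sd = np.zeros(tensor.n_rois)
    if threshold_mode == "pooled":
        sd = np.full(tensor.n_rois, pooled_sd)
        fallback = ()
    else:
        degenerate = roi_sd <= 0
        sd = np.where(degenerate, pooled_sd, roi_sd)
        fallback = tuple(np.flatnonzero(degenerate).tolist())
        if fallback:
            warnings.warn(
                f"{len(fallback)} ROI(s) with zero blank variance classified "
                "with the pooled-blank threshold", stacklevel=2)
    low = blank_mean - n_sd * sd
    high = blank_mean + n_sd * sd
    tm = tensor.trial_mean()
    labels = np.zeros(tm.shape, dtype=np.int8)
    labels[tm > high[:, None]] = ENHANCED
    labels[tm < low[:, None]] = SUPPRESSED
    return ClassifiedResponses(labels=labels, thresholds=np.column_stack([low, high]),
                               trial_mean=tm, n_sd=n_sd,
                               pooled_fallback_rois=fallback)


def filter_rois(classified: ClassifiedResponses) -> np.ndarray:
    """Boolean mask of ROIs with at least one significant (non-zero) label."""
    keep = (classified.labels != NONRESPONSIVE).any(axis=1)
    if not keep.any():
        warnings.warn("no ROI has a significant response; filter is empty",
                      stacklevel=2)
    return keep


def polarity_class(classified: ClassifiedResponses, roi: int) -> str:
    """Polarity of one ROI over the panel.

    pure_enhanced: >=1 enhanced and no suppressed label; pure_suppressed
    symmetric; mixed: at least one of each; silent: no significant label.
    """
    row = classified.labels[roi]
    has_e = (row == ENHANCED).any()
    has_s = (row == SUPPRESSED).any()
    if has_e and has_s:
        return "mixed"
    if has_e:
        return "pure_enhanced"
    if has_s:
        return "pure_suppressed"
    return "silent"


def polarity_fractions(classified: ClassifiedResponses) -> dict:
    """Fractions of pure_enhanced / pure_suppressed / mixed / silent ROIs."""
    classes = [polarity_class(classified, i) for i in range(classified.n_rois)]
    n = len(classes)
    return {c: classes.count(c) / n
            for c in ("pure_enhanced", "pure_suppressed", "mixed", "silent")}


def effective_odorant_count(classified: ClassifiedResponses, roi: int) -> int:
    """Number of stimuli driving the ROI significantly above or below baseline."""
    return int((classified.labels[roi] != NONRESPONSIVE).sum())


# ---------------------------------------------------------------------------
# Sparseness (Treves-Rolls activity ratio)
# ---------------------------------------------------------------------------

def _sparseness(r: np.ndarray) -> float:
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ValueError("responses must be a non-empty 1-D vector")
    if (r < 0).any():
        raise ValueError("sparseness expects non-negative magnitudes")
    denom = np.mean(r ** 2)
    if denom == 0:
        warnings.warn("all-zero response vector: sparseness undefined", stacklevel=3)
        return float("nan")
    return float(np.mean(r) ** 2 / denom)


def population_sparseness(responses, n: int | None = None) -> float:
    """PS = (Σ r_i/n)² / Σ(r_i²/n) over ROIs for one stimulus.

    1 for uniform activity across ROIs, 1/n for a one-hot vector.  Expects
    non-negative magnitudes; all-zero input returns NaN with a warning.
    """
    r = np.asarray(responses, dtype=float)
    if n is not None and n != r.size:
        raise ValueError("n must equal the number of responses")
    return _sparseness(r)


def lifetime_sparseness(responses, m: int | None = None) -> float:
    """LS = (Σ r_j/m)² / Σ(r_j²/m) over stimuli for one ROI (Eq. dual of PS)."""
    r = np.asarray(responses, dtype=float)
    if m is not None and m != r.size:
        raise ValueError("m must equal the number of responses")
    return _sparseness(r)


@dataclass(frozen=True)
class SparsenessReport:
    population_sparseness: np.ndarray  # per stimulus
    lifetime_sparseness: np.ndarray    # per retained ROI
    n_rois: int
    n_stimuli: int
    roi_mask: np.ndarray = None


def sparseness_report(tensor: ResponseTensor, n_sd: float = 3.0,
                      signed: bool = False,
                      roi_mask: np.ndarray | None = None) -> SparsenessReport:
    """Sparseness over retained ROIs using trial-mean response magnitudes.

    By default absolute magnitudes are used so suppressed responses contribute
    to both measures; ``signed=True`` feeds raw signed means instead (only
    meaningful when all retained responses are non-negative).
    """
    if roi_mask is None:
        roi_mask = filter_rois(classify_responses(tensor, n_sd))
    r = tensor.trial_mean()[roi_mask]
    if not signed:
        r = np.abs(r)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ps = np.array([_sparseness(r[:, j]) for j in range(r.shape[1])])
        ls = np.array([_sparseness(r[i, :]) for i in range(r.shape[0])])
    return SparsenessReport(ps, ls, n_rois=int(roi_mask.sum()),
                            n_stimuli=r.shape[1], roi_mask=roi_mask)


# ---------------------------------------------------------------------------
# Ranked tuning curves
# ---------------------------------------------------------------------------

def ranked_tuning_curve(responses) -> np.ndarray:
    """Absolute responses ranked descending and normalized to the largest.

    Ties keep their original stimulus order (stable sort).  An all-zero input
    returns a NaN vector (sentinel).
    """
    r = np.abs(np.asarray(responses, dtype=float))
    if r.ndim != 1 or r.size == 0:
        raise ValueError("responses must be a non-empty 1-D vector")
    if r.max() == 0:
        warnings.warn("all-zero responses: ranked curve undefined", stacklevel=2)
        return np.full(r.size, np.nan)
    order = np.argsort(-r, kind="stable")
    return r[order] / r.max()


def curve_distance(curves) -> np.ndarray:
    """Mean absolute deviation of each curve from the across-stimulus mean curve."""
    c = np.asarray(curves, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need at least two curves of equal length")
    mean_curve = c.mean(axis=0)
    return np.abs(c - mean_curve).mean(axis=1)


# ---------------------------------------------------------------------------
# Representational similarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityMatrix:
    """Pearson correlations between population vectors.

    At ``level='trial'`` the columns are stimulus-trial pairs in stimulus-major
    order (``trials_per_stimulus`` consecutive columns per stimulus); at
    ``level='stimulus_mean'`` one trial-averaged column per stimulus.
    """

    entries: np.ndarray
    stimulus_ids: tuple
    trials_per_stimulus: int
    level: str

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_ids)

    def reorder(self, permutation) -> "SimilarityMatrix":
        """Permute stimuli (rows and columns identically; trial blocks move together)."""
        perm = np.asarray(permutation)
        if sorted(perm.tolist()) != list(range(self.n_stimuli)):
            raise ValueError("permutation must reorder all stimuli")
        t = self.trials_per_stimulus
        cols = (perm[:, None] * t + np.arange(t)[None, :]).ravel()
        return SimilarityMatrix(self.entries[np.ix_(cols, cols)],
                                tuple(self.stimulus_ids[i] for i in perm),
                                t, self.level)


def representational_similarity(tensor: ResponseTensor,
                                level: str = "stimulus_mean",
                                n_sd: float = 3.0,
                                roi_mask: np.ndarray | None = None) -> SimilarityMatrix:
    """Correlation matrix between population vectors of retained ROIs.

    ROIs are filtered by the significance criterion first (or an explicit
    ``roi_mask``).  Zero-variance population vectors yield NaN sentinel
    entries; their count is warned about.
    """
    if level not in ("trial", "stimulus_mean"):
        raise ValueError("level must be 'trial' or 'stimulus_mean'")
    if roi_mask is None:
        roi_mask = filter_rois(classify_responses(tensor, n_sd))
    if int(np.sum(roi_mask)) < 2:
        raise ValueError("need at least two retained ROIs")
    if level == "trial":
        data = tensor.amplitudes[roi_mask].reshape(int(np.sum(roi_mask)), -1)
        t = tensor.n_trials
    else:
        data = tensor.trial_mean()[roi_mask]
        t = 1
    sd = data.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance population "
                      "vector(s); correlations set to NaN", stacklevel=2)
        corr[degenerate, :] = np.nan
        corr[:, degenerate] = np.nan
    valid = ~degenerate
    corr[np.diag_indices_from(corr)] = np.where(valid, 1.0, np.nan)
    return SimilarityMatrix(corr, tuple(tensor.panel.ids), t, level)


def within_stimulus_reliability(matrix: SimilarityMatrix) -> np.ndarray:
    """Per-stimulus mean trial-trial correlation (off-diagonal block mean).

    Requires a trial-level matrix; returns NaN for single-trial blocks.
    """
    if matrix.level != "trial":
        raise ValueError("reliability requires a trial-level similarity matrix")
    t = matrix.trials_per_stimulus
    if t < 2:
        return np.full(matrix.n_stimuli, np.nan)
    out = np.empty(matrix.n_stimuli)
    off = ~np.eye(t, dtype=bool)
    for s in range(matrix.n_stimuli):
        block = matrix.entries[s * t:(s + 1) * t, s * t:(s + 1) * t]
        vals = block[off]
        out[s] = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
    return out


def hierarchical_order(matrix) -> np.ndarray:
    """Leaf ordering from average-linkage clustering on distance 1 − r.

    Accepts a stimulus-level :class:`SimilarityMatrix` or a square correlation
    array.  The returned permutation can be applied to another population's
    matrix (e.g. order boutons by the OSN-derived clustering).
    """
    if isinstance(matrix, SimilarityMatrix):
        if matrix.trials_per_stimulus != 1:
            raise ValueError("hierarchical ordering expects a stimulus-level matrix")
        entries = matrix.entries
    else:
        entries = np.asarray(matrix, dtype=float)
    if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.isfinite(entries).all():
        raise ValueError("similarity matrix contains NaN sentinel entries")
    d = 1.0 - entries
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    return np.asarray(leaves_list(z))


# ---------------------------------------------------------------------------
# Mixture overlap
# ---------------------------------------------------------------------------

def mixture_overlap(a, b, method: str = "max") -> float:
    """Component overlap |a ∩ b| / max(|a|, |b|) (or Jaccard), in [0, 1]."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("component sets must be non-empty")
    inter = len(sa & sb)
    if method == "max":
        return inter / max(len(sa), len(sb))
    if method == "jaccard":
        return inter / len(sa | sb)
    raise ValueError("method must be 'max' or 'jaccard'")


@dataclass(frozen=True)
class OverlapComparison:
    high: np.ndarray          # correlations of pairs with overlap >= threshold
    low: np.ndarray
    mean_high: float
    mean_low: float
    threshold: float
    sizes: tuple


def overlap_group_comparison(matrix: SimilarityMatrix, panel: StimulusPanel,
                             threshold: float = 0.75, sizes=(8, 12),
                             method: str = "max") -> OverlapComparison:
    """Split mixture-pair correlations by component overlap.

    Considers all pairs among stimuli whose component count is in ``sizes``
    (the two largest mixture classes by default) and partitions their
    correlations at the overlap ``threshold``.  Empty groups give NaN means.
    """
    if matrix.trials_per_stimulus != 1:
        raise ValueError("overlap comparison expects a stimulus-level matrix")
    if len(panel) != matrix.n_stimuli:
        raise ValueError("panel does not match the similarity matrix")
    idx = panel.indices_of_size(*sizes)
    stimuli = list(panel)
    high, low = [], []
    for a_pos, i in enumerate(idx):
        for j in idx[a_pos + 1:]:
            r = matrix.entries[i, j]
            if not np.isfinite(r):
                continue
            ov = mixture_overlap(stimuli[i].components, stimuli[j].components,
                                 method=method)
            (high if ov >= threshold else low).append(r)
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    return OverlapComparison(
        high=high, low=low,
        mean_high=float(high.mean()) if high.size else float("nan"),
        mean_low=float(low.mean()) if low.size else float("nan"),
        threshold=threshold, sizes=tuple(sizes))
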