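"""Count-matrix I/O, validation, filtering and library-size normalization.

The central container is :class:`CountMatrix`: a features x samples matrix of
non-negative counts together with a sample -> strain design.  Samples from
the same strain are biological replicates of (nearly) the same genotype, so
the strain labels define the grouping used by every mixed model downstream.

Library sizes are equalized with median-of-ratios size factors: each
sample's factor is the median over features of the ratio between the
sample's count and the feature's geometric mean across samples, computed on
features positive in every sample and then centered to geometric mean 1.
Normalized counts are count/factor -- continuous values suitable for the
compound Poisson model and the transformations, or rounded half-away-from-
zero to integers for the negative binomial model.
"""

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Features x samples count matrix with a sample-to-strain design."""

    values: np.ndarray                    # (G, N) non-negative
    feature_ids: list[str]
    sample_ids: list[str]
    strain_of_sample: np.ndarray          # (N,) strain label per sample

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.strain_of_sample = np.asarray(self.strain_of_sample)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D features x samples matrix")
        g, n = self.values.shape
        if len(self.feature_ids) != g:
            raise ValueError("feature_ids length does not match the matrix")
        if len(self.sample_ids) != n or self.strain_of_sample.shape[0] != n:
            raise ValueError("sample annotation length does not match the matrix")
        if len(set(self.feature_ids)) != g:
            dupes = pd.Index(self.feature_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative count at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}")
        if len(np.unique(self.strain_of_sample)) < 2:
            raise ValueError("at least 2 strains are required")

    # -- design helpers -----------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def strains(self) -> np.ndarray:
        return np.unique(self.strain_of_sample)

    @property
    def replicate_counts(self) -> dict:
        u, c = np.unique(self.strain_of_sample, return_counts=True)
        return dict(zip(u.tolist(), c.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def feature(self, feature_id: str) -> np.ndarray:
        try:
            i = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature id {feature_id!r}") from None
        return self.values[i]


@dataclass(frozen=True)
class SizeFactorVector:
    factors: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "factors", np.asarray(self.factors, dtype=float))
        if np.any(self.factors <= 0):
            raise ValueError("size factors must be positive")


def _read_table(path) -> pd.DataFrame:
    # TSV default; fall back to comma if the header has a single column
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        df = pd.read_csv(path, sep=",", index_col=0)
    return df


def read_counts(counts_path, design_path) -> CountMatrix:
    """Read a delimited count matrix (features x samples) and a design table.

    The design table has columns (sample_id, strain_id); samples are matched
    to matrix columns by id, never by position.
    """
    counts = _read_table(counts_path)
    design = pd.read_csv(design_path, sep=None, engine="python",
                         dtype=str, header=0)
    if design.shape[1] < 2:
        raise ValueError("design file needs two columns: sample_id, strain_id")
    design = design.iloc[:, :2]
    design.columns = ["sample_id", "strain_id"]
    design = design.set_index("sample_id")
    missing = [s for s in counts.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from the design table: {missing}")
    strains = design.loc[counts.columns, "strain_id"].to_numpy()
    return CountMatrix(counts.to_numpy(dtype=float),
                       [str(f) for f in counts.index],
                       [str(s) for s in counts.columns],
                       strains)


def filter_low_expression(cm: CountMatrix, min_count: int, min_samples: int) -> CountMatrix:
    """Keep features with >= ``min_samples`` samples at count >= ``min_count``.

    Example: requiring at least 5 samples with at least 10 counts removes
    features too sparse for the mixed models to be identified.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if min_samples > cm.n_samples:
        raise ValueError(f"min_samples ({min_samples}) exceeds the number of "
                         f"samples ({cm.n_samples})")
    keep = (cm.values >= min_count).sum(axis=1) >= min_samples
    return CountMatrix(cm.values[keep],
                       [f for f, k in zip(cm.feature_ids, keep) if k],
                       list(cm.sample_ids), cm.strain_of_sample)


def compute_size_factors(cm: CountMatrix) -> SizeFactorVector:
    """Median-of-ratios size factors, centered to geometric mean 1.

    Only features positive in every sample enter the per-sample median of
    count / geometric-feature-mean ratios; other features are normalized by
    the resulting factors but do not influence them.
    """
    usable = np.all(cm.values > 0, axis=1)
    if not np.any(usable):
        raise ValueError("no feature is positive in all samples; size factors "
                         "cannot be estimated -- filter low-expression features first")
    sub = cm.values[usable]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.log(sub) - log_geo
    log_factors = np.median(ratios, axis=0)
    log_factors -= log_factors.mean()   # center to geometric mean 1
    return SizeFactorVector(np.exp(log_factors))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def normalize_counts(cm: CountMatrix, sf: SizeFactorVector,
                     round_to_integer: bool = False) -> CountMatrix:
    """Divide each sample by its size factor.

    ``round_to_integer`` rounds half away from zero, producing valid input
    for the NB model; the continuous version feeds the compound Poisson
    model and the transformations.
    """
    if sf.factors.shape[0] != cm.n_samples:
        raise ValueError("size factor vector length does not match the sample count")
    vals = cm.values / sf.factors[np.newaxis, :]
    if round_to_integer:
        vals = _round_half_away(vals)
    return CountMatrix(vals, list(cm.feature_ids), list(cm.sample_ids),
                       cm.strain_of_sample)
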