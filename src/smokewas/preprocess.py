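"""Probe-level QC filters and conversion between intensity, beta and M-value scales.

Methylation arrays report, for every CpG probe and every sample, a
methylated-channel intensity M, an unmethylated-channel intensity U, and a
detection p-value comparing the total signal against background noise.  The
methylation fraction is summarized by the Illumina beta value

    beta = M / (M + U + 100)

whose +100 offset regularizes low-intensity probes, and linear modelling is
done on the logit-base-2 M-value scale

    mvalue = log2(beta / (1 - beta))

which has better homoscedasticity near the 0/1 boundaries.

Quality control drops probes whose detection p-value exceeds a threshold in
more than a given fraction of samples, then removes Y-chromosome probes and
probes physically overlapping SNPs.  X-linked probes are retained, which is
appropriate for single-sex cohorts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import normalize_chromosome

#: Offset in the beta denominator (Illumina convention).
BETA_OFFSET = 100.0

#: Betas are clipped to [BETA_CLIP, 1 - BETA_CLIP] before the logit so that
#: zero-signal probes do not produce infinite M-values.
BETA_CLIP = 1e-6

ANNOTATION_COLUMNS = ["probe_id", "chromosome", "position", "gene", "snp_overlap"]


@dataclass
class IntensityTable:
    """Per-probe, per-sample (M, U, detection-p) triplets.

    The three frames share a probe index (rows) and sample columns.
    """

    m_signal: pd.DataFrame
    u_signal: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("u_signal", "detection_p"):
            other = getattr(self, name)
            if not (other.index.equals(self.m_signal.index)
                    and other.columns.equals(self.m_signal.columns)):
                raise ValueError(f"{name} is not aligned with m_signal")
        dp = self.detection_p.to_numpy()
        if ((dp < 0) | (dp > 1)).any():
            raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.m_signal.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.m_signal.columns

    @property
    def n_probes(self) -> int:
        return self.m_signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.m_signal.shape[1]

    def subset(self, probe_ids) -> "IntensityTable":
        return IntensityTable(
            self.m_signal.loc[probe_ids],
            self.u_signal.loc[probe_ids],
            self.detection_p.loc[probe_ids],
        )

    def to_long(self) -> pd.DataFrame:
        """Long-form TSV layout: probe_id, sample_id, m_signal, u_signal, detection_p."""
        frames = {
            "m_signal": self.m_signal,
            "u_signal": self.u_signal,
            "detection_p": self.detection_p,
        }
        long = None
        for name, frame in frames.items():
            stacked = frame.stack()
            stacked.name = name
            part = stacked.reset_index()
            part.columns = ["probe_id", "sample_id", name]
            long = part if long is None else long.merge(part, on=["probe_id", "sample_id"])
        return long

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "IntensityTable":
        def pivot(col: str) -> pd.DataFrame:
            wide = long.pivot(index="probe_id", columns="sample_id", values=col)
            wide.index.name = None
            wide.columns.name = None
            return wide

        m = pivot("m_signal")
        return cls(m, pivot("u_signal").loc[m.index, m.columns],
                   pivot("detection_p").loc[m.index, m.columns])


@dataclass
class MethylationMatrix:
    """Probe x sample methylation matrix tagged with its scale ('beta' or 'mvalue')."""

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "mvalue"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.scale == "beta":
            v = self.values.to_numpy()
            if ((v < 0) | (v >= 1)).any():
                raise ValueError("beta values must lie in [0, 1)")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def compute_beta(intensities: IntensityTable) -> MethylationMatrix:
    """Beta values from intensity pairs: beta = M / (M + U + 100)."""
    m = intensities.m_signal.to_numpy(float)
    u = intensities.u_signal.to_numpy(float)
    n_bad = int((m < 0).sum() + (u < 0).sum())
    if n_bad:
        raise ValueError(f"negative signal intensities in {n_bad} cells")
    beta = m / (m + u + BETA_OFFSET)
    return MethylationMatrix(
        pd.DataFrame(beta, index=intensities.probe_ids, columns=intensities.sample_ids),
        scale="beta",
    )


def beta_to_m(matrix: MethylationMatrix) -> MethylationMatrix:
    """Logit-base-2 transform, with betas clipped to [1e-6, 1 - 1e-6] first."""
    if matrix.scale != "beta":
        raise ValueError("beta_to_m expects a beta-scale matrix")
    b = matrix.values.to_numpy(float)
    if ((b < 0) | (b > 1)).any():
        raise ValueError("beta values outside [0, 1]")
    b = np.clip(b, BETA_CLIP, 1.0 - BETA_CLIP)
    mv = np.log2(b / (1.0 - b))
    return MethylationMatrix(
        pd.DataFrame(mv, index=matrix.probe_ids, columns=matrix.sample_ids),
        scale="mvalue",
    )


def m_to_beta(matrix: MethylationMatrix) -> MethylationMatrix:
    """Exact inverse of :func:`beta_to_m` (up to the clipping)."""
    if matrix.scale != "mvalue":
        raise ValueError("m_to_beta expects an mvalue-scale matrix")
    mv = matrix.values.to_numpy(float)
    b = np.power(2.0, mv) / (1.0 + np.power(2.0, mv))
    return MethylationMatrix(
        pd.DataFrame(b, index=matrix.probe_ids, columns=matrix.sample_ids),
        scale="beta",
    )


def filter_detection(
    intensities: IntensityTable,
    p_threshold: float = 0.01,
    sample_fraction: float = 0.05,
) -> tuple[IntensityTable, list[str]]:
    """Drop probes with detection p > ``p_threshold`` in more than
    ``sample_fraction`` of samples (strict: count > fraction x n).

    With 34 samples and the defaults, 5% of 34 = 1.7, so a probe failing in 1
    sample is kept and one failing in 2 samples is dropped.

    Returns the filtered table and the list of dropped probe ids.
    """
    for name, v in (("p_threshold", p_threshold), ("sample_fraction", sample_fraction)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {v}")
    if intensities.n_probes == 0:
        raise ValueError("empty intensity table")
    fails = (intensities.detection_p.to_numpy() > p_threshold).sum(axis=1)
    drop = fails > sample_fraction * intensities.n_samples
    dropped = list(intensities.probe_ids[drop])
    kept = intensities.subset(intensities.probe_ids[~drop])
    return kept, dropped


def filter_probes(
    matrix: MethylationMatrix,
    annotation: pd.DataFrame,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Drop Y-chromosome probes and probes overlapping SNPs; keep chrX.

    Reason precedence is chrY before snp_overlap, so a probe that trips both
    rules is reported once, as chrY.

    Returns the filtered matrix and a dropped-probe report with columns
    (probe_id, reason).
    """
    ann = annotation.set_index("probe_id")
    missing = matrix.probe_ids.difference(ann.index)
    if len(missing):
        raise KeyError(f"{len(missing)} probes missing from annotation, e.g. {missing[0]!r}")
    ann = ann.loc[matrix.probe_ids]
    is_y = ann["chromosome"].map(normalize_chromosome).to_numpy() == "Y"
    is_snp = ann["snp_overlap"].astype(bool).to_numpy()
    reasons = np.where(is_y, "chrY", np.where(is_snp, "snp_overlap", ""))
    drop = reasons != ""
    report = pd.DataFrame({
        "probe_id": matrix.probe_ids[drop],
        "reason": reasons[drop],
    }).reset_index(drop=True)
    kept = MethylationMatrix(matrix.values.loc[matrix.probe_ids[~drop]], matrix.scale)
    return kept, report


def normalize_intensities(intensities: IntensityTable) -> IntensityTable:
    """Array-level normalization hook.

    Between-array normalization (e.g. functional normalization) needs raw
    control-probe data that synthetic intensity tables do not carry, so this
    hook is the identity; it keeps the pipeline graph explicit and gives a
    single place to plug a real normalizer in.
    """
    return intensities


def preprocess_pipeline(
    intensities: IntensityTable,
    annotation: pd.DataFrame,
    p_threshold: float = 0.01,
    sample_fraction: float = 0.05,
) -> tuple[MethylationMatrix, MethylationMatrix, pd.DataFrame]:
    """Full preprocessing: detection filter, beta, chrom/SNP filters, M-values.

    Returns (beta matrix, mvalue matrix, dropped-probe report).  The dropped
    report has columns (probe_id, reason) with reasons 'detection_p', 'chrY'
    or 'snp_overlap', in filter order.
    """
    kept, det_dropped = filter_detection(intensities, p_threshold, sample_fraction)
    kept = normalize_intensities(kept)
    beta = compute_beta(kept)
    beta, probe_report = filter_probes(beta, annotation)
    report = pd.concat(
        [pd.DataFrame({"probe_id": det_dropped, "reason": "detection_p"}), probe_report],
        ignore_index=True,
    )
    mvals = beta_to_m(beta)
    if len(report) and len(report) + beta.values.shape[0] != intensities.n_probes:
        warnings.warn("dropped + kept probe counts do not match input count")
    return beta, mvals, report
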