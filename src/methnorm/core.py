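"""Data model for two-colour methylation arrays and pre-normalisation QC.

The Infinium-style arrays measured here carry two probe chemistries:
Type I probes use two probe sequences read in a single colour channel
(one for the methylated allele, M, one for the unmethylated, U), while
Type II probes use a single sequence read in both channels (green = M,
red = U).  Every probe-type-aware operation in the package consults the
:class:`ProbeAnnotation` attached to the intensity container.

Methylation level is summarised either as a beta value
``beta = M / (M + U + offset)`` in [0, 1] or as the logit-like M-value
``log2((M + eps) / (U + eps))``.

QC follows the conventional pre-normalisation filters: a user-supplied
probe exclusion list (cross-hybridising / polymorphic probes), detection
p-value filters on both axes, and a bead-count filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CapabilityError, ValidationError

logger = logging.getLogger(__name__)

DESIGN_TYPES = ("I", "II")
CHANNELS = ("Grn", "Red", "Both")
SPECIAL_CLASSES = ("plain", "dmr", "snp", "chrX_sex")

ANNOTATION_COLUMNS = ["design_type", "channel", "chromosome",
                      "special_class", "cpg_count"]


@dataclass(frozen=True)
class ProbeAnnotation:
    """Per-probe metadata indexed by probe_id.

    Columns: ``design_type`` ("I"/"II"), ``channel`` ("Grn"/"Red" for
    Type I, "Both" for Type II), ``chromosome`` (autosome label, "X",
    "Y"), ``special_class`` ("plain", "dmr", "snp", "chrX_sex") and
    ``cpg_count`` (number of CpGs underlying the probe sequence, the
    stratification variable for subset-based normalisation).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = [c for c in ANNOTATION_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"annotation missing columns {missing}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"duplicate probe ids, e.g. {dup}")
        bad_type = ~t["design_type"].isin(DESIGN_TYPES)
        if bad_type.any():
            raise ValidationError("design_type must be 'I' or 'II'")
        if (t.loc[t["design_type"] == "II", "channel"] != "Both").any():
            raise ValidationError("Type II probes must have channel='Both'")
        if (~t.loc[t["design_type"] == "I", "channel"].isin(["Grn", "Red"])).any():
            raise ValidationError("Type I probes must have channel 'Grn' or 'Red'")
        sexp = t["special_class"] == "chrX_sex"
        if (t.loc[sexp, "chromosome"] != "X").any():
            raise ValidationError("chrX_sex probes must sit on chromosome X")
        if (t["cpg_count"] < 1).any():
            raise ValidationError("cpg_count must be a positive integer")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, probe_ids: Sequence[str]) -> "ProbeAnnotation":
        return ProbeAnnotation(self.table.loc[list(probe_ids)])

    def ids_of_class(self, special_class: str) -> pd.Index:
        return self.table.index[self.table["special_class"] == special_class]

    def is_type(self, design_type: str) -> np.ndarray:
        return (self.table["design_type"] == design_type).to_numpy()


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata indexed by sample_id.

    Expected columns: ``cohort``, ``batch``, ``age`` (years), ``sex``
    ("F"/"M"); optional ``bmi`` (kg/m^2) and ancestry covariates
    ``pc1..pcK`` standing in for genetic principal components.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"duplicate sample ids, e.g. {dup}")
        for col in ("cohort", "age", "sex"):
            if col not in t.columns:
                raise ValidationError(f"sample sheet missing column {col!r}")
        if (~t["sex"].isin(["F", "M"])).any():
            raise ValidationError("sex must be 'F' or 'M'")
        if "bmi" in t.columns:
            bmi = t["bmi"].dropna()
            if (bmi <= 0).any():
                raise ValidationError("bmi must be positive")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)])

    def pc_columns(self) -> list[str]:
        cols = [c for c in self.table.columns if c.startswith("pc")
                and c[2:].isdigit()]
        return sorted(cols, key=lambda c: int(c[2:]))


def _check_matrix(name: str, m: pd.DataFrame | None, probes: pd.Index,
                  samples: pd.Index, *, lo: float | None = 0.0,
                  hi: float | None = None) -> None:
    if m is None:
        return
    if m.shape != (len(probes), len(samples)):
        raise ValidationError(
            f"{name} has shape {m.shape}, expected "
            f"({len(probes)}, {len(samples)})")
    if not m.index.equals(probes) or not m.columns.equals(samples):
        raise ValidationError(f"{name} index/columns do not match annotation "
                              "probe ids / sample ids")
    vals = m.to_numpy()
    if lo is not None and (vals < lo).any():
        raise ValidationError(f"{name} contains values below {lo}")
    if hi is not None and (vals > hi).any():
        raise ValidationError(f"{name} contains values above {hi}")


@dataclass(frozen=True)
class IntensityData:
    """Paired methylated/unmethylated signal plus optional side matrices.

    All matrices are probe x sample DataFrames sharing index and columns
    with the annotation / sample sheet.  ``oob_meth``/``oob_unmeth``
    carry Type I out-of-band signal (read in the opposite colour
    channel; a pure background measurement); rows for Type II probes
    may be NaN.  ``beadcount`` and ``detection_p`` feed the QC filters.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    annotation: ProbeAnnotation
    samples: SampleSheet
    oob_meth: pd.DataFrame | None = None
    oob_unmeth: pd.DataFrame | None = None
    beadcount: pd.DataFrame | None = None
    detection_p: pd.DataFrame | None = None

    def __post_init__(self):
        probes = self.annotation.probe_ids
        sample_ids = self.samples.sample_ids
        _check_matrix("meth", self.meth, probes, sample_ids)
        _check_matrix("unmeth", self.unmeth, probes, sample_ids)
        for name in ("oob_meth", "oob_unmeth"):
            m = getattr(self, name)
            if m is not None:
                if m.shape != (len(probes), len(sample_ids)):
                    raise ValidationError(f"{name} shape mismatch")
                vals = m.to_numpy()
                if np.nanmin(vals, initial=0.0) < 0:
                    raise ValidationError(f"{name} contains negative values")
        _check_matrix("beadcount", self.beadcount, probes, sample_ids)
        _check_matrix("detection_p", self.detection_p, probes, sample_ids,
                      lo=0.0, hi=1.0)

    @property
    def n_probes(self) -> int:
        return len(self.annotation)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_probes(self, probe_ids: Sequence[str]) -> "IntensityData":
        ids = list(probe_ids)
        kw = {}
        for name in ("oob_meth", "oob_unmeth", "beadcount", "detection_p"):
            m = getattr(self, name)
            kw[name] = None if m is None else m.loc[ids]
        return IntensityData(self.meth.loc[ids], self.unmeth.loc[ids],
                             self.annotation.subset(ids), self.samples, **kw)

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityData":
        ids = list(sample_ids)
        kw = {}
        for name in ("oob_meth", "oob_unmeth", "beadcount", "detection_p"):
            m = getattr(self, name)
            kw[name] = None if m is None else m[ids]
        return IntensityData(self.meth[ids], self.unmeth[ids],
                             self.annotation, self.samples.subset(ids), **kw)

    def with_signal(self, meth: pd.DataFrame,
                    unmeth: pd.DataFrame) -> "IntensityData":
        """Return a copy with replaced meth/unmeth matrices."""
        return replace(self, meth=meth, unmeth=unmeth)


@dataclass(frozen=True)
class BetaMatrix:
    """Normalised methylation proportions in [0, 1], probe x sample."""

    values: pd.DataFrame
    annotation: ProbeAnnotation
    samples: SampleSheet
    scale: str = "beta"

    def __post_init__(self):
        _check_matrix("beta", self.values, self.annotation.probe_ids,
                      self.samples.sample_ids, lo=0.0, hi=1.0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        ids = list(sample_ids)
        return BetaMatrix(self.values[ids], self.annotation,
                          self.samples.subset(ids))

    def to_mvalues(self, floor: float = 1e-6) -> "MValueMatrix":
        b = self.values.clip(floor, 1.0 - floor)
        return MValueMatrix(np.log2(b / (1.0 - b)), self.annotation,
                            self.samples)


@dataclass(frozen=True)
class MValueMatrix:
    """log2 methylated/unmethylated ratios, probe x sample, finite."""

    values: pd.DataFrame
    annotation: ProbeAnnotation
    samples: SampleSheet
    scale: str = "mvalue"

    def __post_init__(self):
        if self.values.shape != (len(self.annotation), len(self.samples)):
            raise ValidationError("M-value matrix shape mismatch")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("M-values must be finite")

    def subset_samples(self, sample_ids: Sequence[str]) -> "MValueMatrix":
        ids = list(sample_ids)
        return MValueMatrix(self.values[ids], self.annotation,
                            self.samples.subset(ids))


@dataclass(frozen=True)
class QCReport:
    probes_removed_exclusion_list: int = 0
    probes_removed_detection: int = 0
    samples_removed_detection: int = 0
    probes_removed_beadcount: int = 0
    probes_remaining: int = 0
    samples_remaining: int = 0

    def __post_init__(self):
        for f, v in self.__dict__.items():
            if v < 0:
                raise ValidationError(f"QCReport.{f} negative")


# ---------------------------------------------------------------------------
# conversions

def beta_from_intensities(data: IntensityData,
                          offset: float = 100.0) -> BetaMatrix:
    """beta = M / (M + U + offset), elementwise.

    The additive offset regularises low-intensity probes; 100 is the
    conventional choice for Infinium arrays.
    """
    if offset < 0:
        raise ValidationError("offset must be non-negative")
    m = data.meth.to_numpy(dtype=float)
    u = data.unmeth.to_numpy(dtype=float)
    denom = m + u + offset
    with np.errstate(invalid="ignore"):
        b = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), 0.0)
    values = pd.DataFrame(b, index=data.meth.index, columns=data.meth.columns)
    return BetaMatrix(values, data.annotation, data.samples)


def mvalue_from_intensities(data: IntensityData,
                            eps: float = 1.0) -> MValueMatrix:
    """M-value = log2((M + eps) / (U + eps)); eps > 0 keeps it finite."""
    if eps <= 0:
        raise ValidationError("eps must be positive")
    m = data.meth.to_numpy(dtype=float)
    u = data.unmeth.to_numpy(dtype=float)
    values = pd.DataFrame(np.log2((m + eps) / (u + eps)),
                          index=data.meth.index, columns=data.meth.columns)
    return MValueMatrix(values, data.annotation, data.samples)


# ---------------------------------------------------------------------------
# QC filters
#
# "More than" thresholds are strict: a probe failing in exactly 1% of
# samples is kept, one failing in more than 1% is removed.

def filter_probes_by_detection(detp: pd.DataFrame,
                               sample_fraction: float = 0.01,
                               p_threshold: float = 0.05) -> pd.Index:
    """Keep probes whose detection p exceeds ``p_threshold`` in at most
    ``sample_fraction`` of samples."""
    if detp.size == 0:
        raise ValidationError("empty detection-p matrix")
    vals = detp.to_numpy()
    if (vals < 0).any() or (vals > 1).any():
        raise ValidationError("detection p-values must lie in [0, 1]")
    frac_fail = (vals > p_threshold).mean(axis=1)
    keep = frac_fail <= sample_fraction
    return detp.index[keep]


def filter_samples_by_detection(detp: pd.DataFrame,
                                probe_fraction: float = 0.01,
                                p_threshold: float = 0.05) -> pd.Index:
    """Mirror of the probe filter on the sample axis."""
    if detp.size == 0:
        raise ValidationError("empty detection-p matrix")
    vals = detp.to_numpy()
    if (vals < 0).any() or (vals > 1).any():
        raise ValidationError("detection p-values must lie in [0, 1]")
    frac_fail = (vals > p_threshold).mean(axis=0)
    keep = frac_fail <= probe_fraction
    return detp.columns[keep]


def filter_probes_by_beadcount(beadcount: pd.DataFrame | None,
                               min_beads: int = 3,
                               sample_fraction: float = 0.05,
                               all_probes: pd.Index | None = None) -> pd.Index:
    """Remove probes with bead count below ``min_beads`` in more than
    ``sample_fraction`` of samples.  A missing matrix skips the filter
    (logged) and returns all probes."""
    if beadcount is None:
        logger.warning("no beadcount matrix: bead-count filter skipped")
        if all_probes is None:
            raise ValidationError(
                "all_probes required when beadcount is missing")
        return all_probes
    vals = beadcount.to_numpy()
    if (vals < 0).any():
        raise ValidationError("bead counts must be non-negative")
    frac_low = (vals < min_beads).mean(axis=1)
    keep = frac_low <= sample_fraction
    return beadcount.index[keep]


def drop_probe_exclusion_list(annotation: ProbeAnnotation,
                              exclusion_ids: Iterable[str]) -> pd.Index:
    """Keep probes not named in the exclusion list (cross-hybridising /
    polymorphic probes supplied by the user).  Unknown ids are ignored
    with a logged count."""
    excl = set(exclusion_ids)
    known = excl & set(annotation.probe_ids)
    unknown = len(excl) - len(known)
    if unknown:
        logger.warning("%d exclusion-list ids not present on the array "
                       "(ignored)", unknown)
    return annotation.probe_ids[~annotation.probe_ids.isin(known)]


def run_qc(data: IntensityData,
           exclusion_ids: Iterable[str] = (),
           detection_sample_fraction: float = 0.01,
           detection_probe_fraction: float = 0.01,
           detection_p_threshold: float = 0.05,
           beadcount_min: int = 3,
           beadcount_sample_fraction: float = 0.05,
           ) -> tuple[IntensityData, QCReport]:
    """Apply the pre-normalisation filters in order: exclusion list,
    probe detection filter, sample detection filter, bead-count filter.

    The sequence is applied once, without re-iterating earlier filters
    after sample removal.
    """
    n_probes0, n_samples0 = data.n_probes, data.n_samples

    keep = drop_probe_exclusion_list(data.annotation, exclusion_ids)
    removed_excl = n_probes0 - len(keep)
    data = data.subset_probes(keep) if removed_excl else data

    removed_det_p = 0
    removed_det_s = 0
    if data.detection_p is not None:
        keep_p = filter_probes_by_detection(
            data.detection_p, detection_sample_fraction, detection_p_threshold)
        removed_det_p = data.n_probes - len(keep_p)
        if removed_det_p:
            data = data.subset_probes(keep_p)
        keep_s = filter_samples_by_detection(
            data.detection_p, detection_probe_fraction, detection_p_threshold)
        removed_det_s = data.n_samples - len(keep_s)
        if removed_det_s:
            data = data.subset_samples(keep_s)
    else:
        logger.warning("no detection-p matrix: detection filters skipped")

    keep_b = filter_probes_by_beadcount(
        data.beadcount, beadcount_min, beadcount_sample_fraction,
        all_probes=data.annotation.probe_ids)
    removed_bead = data.n_probes - len(keep_b)
    if removed_bead:
        data = data.subset_probes(keep_b)

    report = QCReport(
        probes_removed_exclusion_list=removed_excl,
        probes_removed_detection=removed_det_p,
        samples_removed_detection=removed_det_s,
        probes_removed_beadcount=removed_bead,
        probes_remaining=data.n_probes,
        samples_remaining=data.n_samples,
    )
    logger.info("QC: %d probes and %d samples remain (removed %d/%d/%d "
                "probes by exclusion/detection/beadcount, %d samples)",
                report.probes_remaining, report.samples_remaining,
                removed_excl, removed_det_p, removed_bead, removed_det_s)
    return data, report


def harmonise_cohorts(datasets: Sequence[IntensityData]) -> IntensityData:
    """Combine cohorts on the intersection of their probe sets.

    Probe order follows the first dataset; samples are concatenated in
    input order with cohort labels preserved.  Optional matrices are
    combined only when present in every dataset.
    """
    if len(datasets) < 2:
        raise ValidationError("harmonise_cohorts needs at least two datasets")
    common = datasets[0].annotation.probe_ids
    for d in datasets[1:]:
        common = common[common.isin(d.annotation.probe_ids)]
    if len(common) == 0:
        raise ValidationError("no probes shared across datasets")

    all_samples = pd.Index(np.concatenate(
        [d.samples.sample_ids.to_numpy() for d in datasets]))
    if all_samples.has_duplicates:
        dup = all_samples[all_samples.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate sample ids across cohorts: {dup}")

    ref = datasets[0].annotation.subset(common).table
    for d in datasets[1:]:
        other = d.annotation.subset(common).table
        if not ref[ANNOTATION_COLUMNS].equals(other[ANNOTATION_COLUMNS]):
            raise ValidationError(
                "annotations disagree on shared probes across datasets")

    subs = [d.subset_probes(common) for d in datasets]

    def _concat(attr):
        mats = [getattr(s, attr) for s in subs]
        if any(m is None for m in mats):
            return None
        return pd.concat(mats, axis=1)

    sheet = SampleSheet(pd.concat([s.samples.table for s in subs], axis=0))
    return IntensityData(
        meth=_concat("meth"), unmeth=_concat("unmeth"),
        annotation=subs[0].annotation, samples=sheet,
        oob_meth=_concat("oob_meth"), oob_unmeth=_concat("oob_unmeth"),
        beadcount=_concat("beadcount"), detection_p=_concat("detection_p"))
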