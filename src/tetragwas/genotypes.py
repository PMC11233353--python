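"""Dosage-genotype ingestion, marker QC and marker summary statistics.

Genotypes for an autotetraploid panel are held as integer allele dosages
(0..4 copies of the alternate allele) in a markers x samples matrix, the
representation used by dosage-based GWAS tools for polyploids. Missing
calls are ``NaN``. The QC chain mirrors the standard dosage-marker filters:
biallelic-only at read time, then monomorphic removal, per-marker
missingness, minor allele frequency and maximum genotype-class frequency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

PLOIDY = 4

MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "panel"]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class DosageMatrix:
    """Markers x samples allele-dosage matrix with per-marker metadata.

    ``values`` is float so missing entries can be ``NaN``; non-missing
    entries are integers in 0..4. ``markers`` carries one row per marker
    (columns ``id, chrom, pos, ref, alt, panel``) aligned with the rows of
    ``values`` and sorted by (chrom, pos).
    """

    values: np.ndarray
    samples: list[str]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D markers x samples array")
        if self.values.shape != (len(self.markers), len(self.samples)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > PLOIDY):
            raise ValueError("dosages must lie in 0..4 or be NaN")
        self.markers = self.markers.reset_index(drop=True)
        order = np.lexsort((self.markers["pos"].to_numpy(),
                            self.markers["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(order))):
            self.markers = self.markers.iloc[order].reset_index(drop=True)
            self.values = self.values[order]

    @property
    def n_markers(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.values).mean(axis=1)

    def alt_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency, mean dosage / ploidy."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=1) / PLOIDY

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def max_genotype_freq(self) -> np.ndarray:
        """Per-marker modal dosage-class frequency over non-missing calls."""
        out = np.full(self.n_markers, np.nan)
        for i, row in enumerate(self.values):
            obs = row[~np.isnan(row)]
            if obs.size == 0:
                continue
            counts = np.bincount(obs.astype(int), minlength=PLOIDY + 1)
            out[i] = counts.max() / obs.size
        return out

    def take_markers(self, index: np.ndarray) -> "DosageMatrix":
        return DosageMatrix(self.values[index],
                            list(self.samples),
                            self.markers.iloc[np.asarray(index)])

    def take_samples(self, index: np.ndarray) -> "DosageMatrix":
        index = np.asarray(index)
        return DosageMatrix(self.values[:, index],
                            [self.samples[i] for i in index],
                            self.markers)

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the marker mean."""
        vals = self.values.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(vals, axis=1)
        means = np.where(np.isfinite(means), means, 0.0)
        nan_r, nan_c = np.nonzero(np.isnan(vals))
        vals[nan_r, nan_c] = means[nan_r]
        return vals


@dataclass(frozen=True)
class QCThresholds:
    """Marker/genotype QC thresholds.

    Genotype-level: calls with read depth below ``min_dp`` or genotype
    quality below ``min_gq`` are set missing at read time; sites with
    QualByDepth below ``min_qd`` are dropped. Marker-level: missingness,
    MAF and modal genotype-class frequency.
    """

    min_dp: int = 15
    min_gq: int = 10
    min_qd: float = 2.0
    max_missing: float = 0.20
    min_maf: float = 0.01
    max_geno_freq: float = 0.98

    def __post_init__(self) -> None:
        if not (0 <= self.max_missing <= 1 and 0 <= self.min_maf <= 0.5
                and 0 < self.max_geno_freq <= 1):
            raise ValueError("QC thresholds out of range")


@dataclass
class QCReport:
    """Counts of markers removed by each rule, in application order."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_output(self) -> int:
        return self.n_input - sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows.append(("output", self.n_output))
        return pd.DataFrame(rows, columns=["stage", "n_markers"])


def read_dosage_vcf(path, thresholds: QCThresholds | None = None,
                    panel: str = "GBS") -> DosageMatrix:
    """Read tetraploid genotypes from a VCF into a :class:`DosageMatrix`.

    Dosage is the count of alternate alleles in the ploidy-4 GT call; the
    DS format field is used where GT is absent. Multi-allelic records are
    excluded (count logged). When ``thresholds`` is given, genotype calls
    with DP < min_dp or GQ < min_gq are set missing and sites with INFO
    QD < min_qd are dropped.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    rows, meta = [], []
    n_multi = n_lowqd = 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multi += 1
            continue
        if thresholds is not None:
            qd = rec.info.get("QD")
            if qd is not None and float(qd) < thresholds.min_qd:
                n_lowqd += 1
                continue
        dose = np.full(len(samples), np.nan)
        for j, name in enumerate(samples):
            call = rec.samples[name]
            gt = call.get("GT")
            if gt is not None and any(a is not None for a in gt):
                if len(gt) != PLOIDY:
                    raise ValueError(
                        f"{path}: ploidy {len(gt)} at {rec.chrom}:{rec.pos}, "
                        f"expected {PLOIDY}")
                if any(a is None for a in gt) or max(gt) > 1 or min(gt) < 0:
                    raise ValueError(
                        f"{path}: invalid allele codes {gt} for biallelic "
                        f"site {rec.chrom}:{rec.pos}")
                d = float(sum(gt))
            else:
                ds = call.get("DS")
                d = np.nan if ds is None else float(ds)
            if thresholds is not None and np.isfinite(d):
                dp, gq = call.get("DP"), call.get("GQ")
                if (dp is not None and dp < thresholds.min_dp) or \
                   (gq is not None and gq < thresholds.min_gq):
                    d = np.nan
            dose[j] = d
        rows.append(dose)
        meta.append((rec.id or f"{rec.chrom}_{rec.pos}", rec.chrom, rec.pos,
                     rec.ref, rec.alts[0], panel))
    vcf.close()
    if n_multi:
        logger.info("read_dosage_vcf: excluded %d multi-allelic records", n_multi)
    if n_lowqd:
        logger.info("read_dosage_vcf: excluded %d records with QD below threshold",
                    n_lowqd)
    markers = pd.DataFrame(meta, columns=MARKER_COLUMNS)
    values = np.array(rows) if rows else np.empty((0, len(samples)))
    return DosageMatrix(values, samples, markers)


def qc_filter(dm: DosageMatrix,
              thresholds: QCThresholds | None = None
              ) -> tuple[DosageMatrix, QCReport]:
    """Apply the marker QC chain and report per-rule removals.

    Rules in order: monomorphic, missingness > max_missing, MAF < min_maf,
    modal dosage-class frequency > max_geno_freq. A marker violating
    several rules is attributed to the first in this order.
    """
    t = thresholds or QCThresholds()
    report = QCReport(n_input=dm.n_markers)
    keep = np.ones(dm.n_markers, dtype=bool)

    n_classes = np.array([np.unique(r[~np.isnan(r)]).size for r in dm.values])
    mono = n_classes <= 1
    report.removed["monomorphic"] = int(mono.sum())
    keep &= ~mono

    miss = (dm.missing_fraction() > t.max_missing) & keep
    report.removed["missingness"] = int(miss.sum())
    keep &= ~miss

    low_maf = (dm.maf() < t.min_maf) & keep
    report.removed["maf"] = int(low_maf.sum())
    keep &= ~low_maf

    high_geno = (dm.max_genotype_freq() > t.max_geno_freq) & keep
    report.removed["max_geno_freq"] = int(high_geno.sum())
    keep &= ~high_geno

    if not keep.any():
        warnings.warn("qc_filter removed every marker", stacklevel=2)
    return dm.take_markers(np.nonzero(keep)[0]), report


def snp_rate(chrom_length_bp: int, snp_count: int) -> int | None:
    """Average genomic distance per SNP (bp), rounded to nearest integer."""
    if snp_count <= 0:
        return None
    return int(round(chrom_length_bp / snp_count))


def density_bins(markers: pd.DataFrame, bin_bp: float = 1e6) -> pd.DataFrame:
    """Per-chromosome marker counts in half-open bins [k*bin, (k+1)*bin)."""
    out = []
    for chrom, grp in markers.groupby("chrom", sort=True):
        idx = (grp["pos"].to_numpy() // int(bin_bp)).astype(int)
        counts = np.bincount(idx)
        for k, c in enumerate(counts):
            out.append((chrom, int(k * bin_bp), int((k + 1) * bin_bp), int(c)))
    return pd.DataFrame(out, columns=["chrom", "bin_start", "bin_end", "count"])


def tstv(markers: pd.DataFrame) -> float:
    """Transition/transversion ratio over biallelic SNPs (A<->G, C<->T vs rest)."""
    pairs = list(zip(markers["ref"], markers["alt"]))
    ts = sum(p in _TRANSITIONS for p in pairs)
    tv = len(pairs) - ts
    if tv == 0:
        warnings.warn("no transversions observed; Ts/Tv is infinite", stacklevel=2)
        return float("inf")
    return ts / tv


def read_gene_intervals(path, fmt: str | None = None) -> pd.DataFrame:
    """Read gene intervals as 1-based inclusive (chrom, start, end).

    BED input (0-based half-open) is converted; a 3/4-column TSV with
    header is taken as already 1-based inclusive.
    """
    path = str(path)
    if fmt is None:
        fmt = "bed" if path.endswith(".bed") else "tsv"
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        df["start"] = df["start"] + 1  # BED start is 0-based
    else:
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns=str.lower)[["chrom", "start", "end"]]
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts)
    ms, me = [], []
    for s, e in zip(starts[order], ends[order]):
        if ms and s <= me[-1] + 1:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.array(ms), np.array(me)


def _in_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray):
    """Membership of positions in merged 1-based inclusive intervals."""
    if starts.size == 0:
        return np.zeros(pos.size, dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    res = np.zeros(pos.size, dtype=bool)
    res[ok] = pos[ok] <= ends[idx[ok]]
    return res


def classify_location(markers: pd.DataFrame, genes: pd.DataFrame,
                      flank_bp: int = 5000) -> pd.Series:
    """Classify markers as genic / gene_associated / intergenic.

    Genic: position inside a gene body (1-based inclusive). Gene-associated:
    within ``flank_bp`` (inclusive) of a gene boundary but not genic.
    Genic takes precedence over the flank of a neighbouring gene.
    """
    result = pd.Series("intergenic", index=markers.index, dtype=object)
    for chrom, grp in markers.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        pos = grp["pos"].to_numpy()
        gs, ge = _merge_intervals(g["start"].to_numpy(), g["end"].to_numpy())
        genic = _in_intervals(pos, gs, ge)
        fs, fe = _merge_intervals(g["start"].to_numpy() - flank_bp,
                                  g["end"].to_numpy() + flank_bp)
        near = _in_intervals(pos, fs, fe)
        lab = np.where(genic, "genic",
                       np.where(near, "gene_associated", "intergenic"))
        result.loc[grp.index] = lab
    return result


def location_summary(classes: pd.Series) -> pd.Series:
    """Percentage of markers per location class (1 dp)."""
    pct = 100 * classes.value_counts() / len(classes)
    return pct.round(1)


def effect_summary(counts: dict[str, int] | pd.Series) -> pd.DataFrame:
    """Per-category SNP counts and percentages (2 dp) for one effect block."""
    s = pd.Series(counts, dtype=float)
    if (s < 0).any():
        raise ValueError("negative counts")
    total = s.sum()
    if total == 0:
        raise ValueError("zero total count")
    from .ld import round_half_up
    return pd.DataFrame({"count": s.astype(int),
                         "percent": (100 * s / total).map(
                             lambda v: round_half_up(v, 2))})


def non_intergenic_percent(region_counts: dict[str, int],
                           intergenic_category: str = "INTERGENIC") -> float:
    """100 minus the intergenic percentage of an effect-region block (1 dp)."""
    from .ld import round_half_up
    tab = effect_summary(region_counts)
    return round_half_up(100 - tab.loc[intergenic_category, "percent"], 1)


def missense_silent_ratio(missense_percent: float, silent_percent: float) -> float:
    """Missense-to-silent ratio from block percentages (2 dp)."""
    return round(missense_percent / silent_percent, 2)
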