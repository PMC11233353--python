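"""Synthetic tetraploid panels with known structure, LD and planted QTL.

The generator provides ground truth for every downstream stage:

* subpopulation allele frequencies follow a Balding-Nichols model around a
  common ancestral frequency with divergence ``fst``;
* each sample is the sum of four haplotypes; along a chromosome the latent
  uniform driving each haplotype is copied from the previous marker with
  probability ``exp(-ld_rho_per_bp * distance)`` (first-order Markov), so
  the correlation between markers decays as ``exp(-rho * d)`` while the
  marginal frequency at every marker is preserved;
* phenotypes combine planted QTL under a chosen gene-action model, a
  polygenic term with covariance proportional to the realized GRM, and
  environment / replicate / residual noise scaled to hit the requested
  heritabilities.

Defaults mirror the stated validation world: 300 samples in 3
subpopulations at Fst 0.3, 2000 markers, four environments with two
replicates (the two-site x two-year, two-replicate trial design of a
typical tetraploid potato panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MARKER_COLUMNS, PLOIDY, DosageMatrix

GENE_ACTIONS = ("additive", "general", "1-dom-alt", "1-dom-ref",
                "2-dom-alt", "2-dom-ref", "diplo-general", "diplo-additive")

# Scalar genotype-value maps used when planting QTL. "general" and
# "diplo-general" are arbitrary non-additive class maps (any fixed map is a
# valid member of those model families); dominance maps are thresholds on
# alt-allele copy number.
_QTL_VALUE_MAPS = {
    "additive": {0: 0.0, 1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0},
    "general": {0: 0.0, 1: 0.4, 2: 1.6, 3: 1.8, 4: 3.0},
    "1-dom-alt": {0: 0.0, 1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0},
    "1-dom-ref": {0: 1.0, 1: 1.0, 2: 1.0, 3: 1.0, 4: 0.0},
    "2-dom-alt": {0: 0.0, 1: 0.0, 2: 1.0, 3: 1.0, 4: 1.0},
    "2-dom-ref": {0: 1.0, 1: 1.0, 2: 1.0, 3: 0.0, 4: 0.0},
    "diplo-general": {0: 0.0, 1: 1.0, 2: 1.0, 3: 1.0, 4: 2.4},
    "diplo-additive": {0: 0.0, 1: 1.0, 2: 1.0, 3: 1.0, 4: 2.0},
}


@dataclass(frozen=True)
class SimConfig:
    """Panel-simulation parameters (ploidy fixed at 4)."""

    n_samples: int = 300
    n_subpops: int = 3
    fst: float = 0.3
    n_chrom: int = 4
    chrom_length_bp: int = 60_000_000
    n_markers_per_chrom: int = 500
    ld_rho_per_bp: float = 1e-6
    missing_rate: float = 0.05
    ploidy: int = PLOIDY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy != PLOIDY:
            raise ValueError("only tetraploid (ploidy 4) panels are supported")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_markers_per_chrom > self.chrom_length_bp:
            raise ValueError("more markers than base pairs on a chromosome")


@dataclass(frozen=True)
class QtlSpec:
    chrom: str
    pos: int
    gene_action: str = "additive"
    effect: float = 1.0

    def __post_init__(self) -> None:
        if self.gene_action not in GENE_ACTIONS:
            raise ValueError(f"unknown gene action {self.gene_action!r}")


@dataclass(frozen=True)
class TraitConfig:
    """Planted-QTL trait parameters.

    When ``h2_qtl``/``h2_polygenic`` are given, QTL and polygenic values
    are rescaled so the per-plot genetic variance fractions match them;
    the non-genetic within-environment variance 1 - h2_qtl - h2_polygenic
    is split between replicate effects (``rep_var_share``) and residual.
    With ``standardize=False`` raw effect sizes and the explicit variance
    fields are used unchanged (e.g. for noise-free limits).
    """

    name: str = "trait"
    qtl: tuple[QtlSpec, ...] = ()
    h2_qtl: float = 0.2
    h2_polygenic: float = 0.3
    n_environments: int = 4
    n_replicates: int = 2
    env_var: float = 0.25
    rep_var_share: float = 0.1
    standardize: bool = True
    sigma2_rep: float = 0.0
    sigma2_resid: float = 0.0
    sigma2_polygenic: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.standardize and not 0 <= self.h2_qtl + self.h2_polygenic < 1:
            raise ValueError("h2_qtl + h2_polygenic must lie in [0, 1)")


@dataclass
class SimPanel:
    """A simulated panel: dosages plus the ground truth that produced them."""

    dosages: DosageMatrix
    subpop_labels: np.ndarray
    founder_freqs: np.ndarray  # (n_markers, n_subpops)
    config: SimConfig

    @property
    def markers(self) -> pd.DataFrame:
        return self.dosages.markers


def _marker_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n strictly increasing positions in 1..length."""
    pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
    return pos


def simulate_population(config: SimConfig) -> SimPanel:
    """Draw a structured tetraploid panel under the Balding-Nichols + Markov-LD model."""
    rng = np.random.default_rng(config.seed)
    n, s = config.n_samples, config.n_subpops
    labels = np.sort(rng.integers(0, s, size=n)) if s > 1 else np.zeros(n, int)
    # ensure every subpopulation is non-empty
    labels[:s] = np.arange(s)
    labels = np.sort(labels)

    all_dose, meta, all_freqs = [], [], []
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1:02d}"
        m = config.n_markers_per_chrom
        pos = _marker_positions(rng, m, config.chrom_length_bp)
        p_anc = rng.uniform(0.05, 0.95, size=m)
        if config.fst > 0:
            a = p_anc * (1 - config.fst) / config.fst
            b = (1 - p_anc) * (1 - config.fst) / config.fst
            freqs = rng.beta(a[:, None], b[:, None], size=(m, s))
            freqs = np.clip(freqs, 1e-4, 1 - 1e-4)
        else:
            freqs = np.repeat(p_anc[:, None], s, axis=1)

        # latent-uniform Markov copying along each of the 4*n haplotypes
        copy_p = np.exp(-config.ld_rho_per_bp * np.diff(pos))
        n_hap = n * PLOIDY
        u = np.empty((m, n_hap))
        u[0] = rng.random(n_hap)
        for j in range(1, m):
            fresh = rng.random(n_hap)
            keep = rng.random(n_hap) < copy_p[j - 1]
            u[j] = np.where(keep, u[j - 1], fresh)
        hap_p = freqs[:, labels].repeat(PLOIDY, axis=1)  # (m, n*4)
        alleles = (u < hap_p).astype(np.int8)
        dose = alleles.reshape(m, n, PLOIDY).sum(axis=2).astype(float)

        if config.missing_rate > 0:
            mask = rng.random((m, n)) < config.missing_rate
            dose[mask] = np.nan

        ref, alt = _random_alleles(rng, m)
        for j in range(m):
            meta.append((f"{chrom}_{pos[j]}", chrom, int(pos[j]),
                         ref[j], alt[j], "SIM"))
        all_dose.append(dose)
        all_freqs.append(freqs)

    markers = pd.DataFrame(meta, columns=MARKER_COLUMNS)
    dm = DosageMatrix(np.vstack(all_dose),
                      [f"S{i + 1:04d}" for i in range(n)], markers)
    return SimPanel(dm, labels, np.vstack(all_freqs), config)


def _random_alleles(rng: np.random.Generator, m: int):
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
    return bases[ref_i], bases[alt_i]


def qtl_genetic_values(panel: SimPanel, qtl: tuple[QtlSpec, ...]) -> np.ndarray:
    """Sum of planted-QTL contributions per sample (missing dosages mean-imputed)."""
    imputed = panel.dosages.imputed()
    markers = panel.markers
    g = np.zeros(panel.dosages.n_samples)
    for q in qtl:
        hit = (markers["chrom"] == q.chrom) & (markers["pos"] == q.pos)
        if not hit.any():
            raise ValueError(f"QTL at {q.chrom}:{q.pos} does not coincide "
                             "with a simulated marker")
        row = imputed[hit.idxmax()]
        vmap = _QTL_VALUE_MAPS[q.gene_action]
        classes = np.clip(np.rint(row), 0, PLOIDY).astype(int)
        g += q.effect * np.vectorize(vmap.get)(classes)
    return g


def simulate_phenotypes(panel: SimPanel, tcfg: TraitConfig
                        ) -> tuple[pd.DataFrame, dict]:
    """Plot-level phenotypes plus generation-time truth.

    Returns a long table (genotype, environment, replicate, <trait>) and a
    dict with the genotypic values and realized variance components.
    """
    from .popstruct import compute_grm  # deferred: avoids import cycle

    rng = np.random.default_rng(tcfg.seed)
    n = panel.dosages.n_samples
    ids = panel.dosages.samples

    q_raw = qtl_genetic_values(panel, tcfg.qtl) if tcfg.qtl else np.zeros(n)
    grm = compute_grm(panel.dosages)
    evals, evecs = np.linalg.eigh(grm.values)
    evals = np.clip(evals, 0, None)
    u_raw = evecs @ (np.sqrt(evals) * rng.standard_normal(n))
    # orthogonalize against the QTL component so the realized variance
    # decomposition matches the requested h2 fractions exactly
    if np.var(q_raw) > 0:
        qc = q_raw - q_raw.mean()
        u_raw = u_raw - qc * (u_raw @ qc) / (qc @ qc)

    if tcfg.standardize:
        q = _scale_to_var(q_raw, tcfg.h2_qtl)
        u = _scale_to_var(u_raw, tcfg.h2_polygenic)
        noise_var = 1.0 - tcfg.h2_qtl - tcfg.h2_polygenic
        s2_rep = tcfg.rep_var_share * noise_var
        s2_res = noise_var - s2_rep
    else:
        q = q_raw
        u = _scale_to_var(u_raw, tcfg.sigma2_polygenic)
        s2_rep, s2_res = tcfg.sigma2_rep, tcfg.sigma2_resid
    g = q + u

    rows = []
    for e in range(tcfg.n_environments):
        env = f"ENV{e + 1}"
        env_eff = rng.normal(0, np.sqrt(tcfg.env_var)) if tcfg.env_var > 0 else 0.0
        for r in range(tcfg.n_replicates):
            rep_eff = rng.normal(0, np.sqrt(s2_rep)) if s2_rep > 0 else 0.0
            resid = (rng.normal(0, np.sqrt(s2_res), size=n)
                     if s2_res > 0 else np.zeros(n))
            vals = g + env_eff + rep_eff + resid
            rows.append(pd.DataFrame({"genotype": ids, "environment": env,
                                      "replicate": r + 1, tcfg.name: vals}))
    plots = pd.concat(rows, ignore_index=True)
    var_g = float(np.var(g))
    truth = {
        "genotypic_value": pd.Series(g, index=ids),
        "qtl_value": pd.Series(q, index=ids),
        "polygenic_value": pd.Series(u, index=ids),
        "sigma2_g": var_g,
        "sigma2_rep": s2_rep,
        "sigma2_resid": s2_res,
        "h2_plot": var_g / (var_g + s2_rep + s2_res)
        if var_g + s2_rep + s2_res > 0 else np.nan,
    }
    return plots, truth


def _scale_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    v = np.var(x)
    if target_var == 0 or v == 0:
        return np.zeros_like(x)
    return (x - x.mean()) * np.sqrt(target_var / v)


def dosage_to_gt(d: float) -> str:
    """Dosage -> unphased ploidy-4 GT string (3 -> ``0/1/1/1``)."""
    if not np.isfinite(d):
        return "./././."
    d = int(round(d))
    return "/".join(["0"] * (PLOIDY - d) + ["1"] * d)


def write_panel(panel: SimPanel, phenotypes: pd.DataFrame | None,
                vcf_path, bed_path=None, pheno_path=None,
                seed: int | None = None) -> None:
    """Write the panel as VCF (+ marker BED, + phenotype TSV).

    The VCF carries ploidy-4 GT and numeric DS per genotype, plus DP/GQ
    per genotype and a QD INFO field (drawn from plausible post-calling
    distributions) so that filter code can be exercised on simulated data.
    ``read_dosage_vcf`` on the output reproduces the dosages exactly.
    """
    rng = np.random.default_rng(panel.config.seed if seed is None else seed)
    dm = panel.dosages
    chrom_len = panel.config.chrom_length_bp
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dm.markers["chrom"].unique():
            fh.write(f"##contig=<ID={chrom},length={chrom_len}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="QualByDepth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dm.samples) + "\n")
        for i, mk in dm.markers.iterrows():
            qd = 2.0 + rng.gamma(4.0, 5.0)
            dp = 15 + rng.poisson(45, size=dm.n_samples)
            gq = 10 + rng.integers(0, 90, size=dm.n_samples)
            cells = []
            for j in range(dm.n_samples):
                d = dm.values[i, j]
                ds = "." if not np.isfinite(d) else f"{int(round(d))}"
                cells.append(f"{dosage_to_gt(d)}:{ds}:{dp[j]}:{gq[j]}")
            fh.write(f"{mk.chrom}\t{mk.pos}\t{mk.id}\t{mk.ref}\t{mk.alt}\t"
                     f"99\tPASS\tQD={qd:.2f}\tGT:DS:DP:GQ\t" + "\t".join(cells) + "\n")
    if bed_path is not None:
        bed = pd.DataFrame({"chrom": dm.markers["chrom"],
                            "start": dm.markers["pos"] - 1,
                            "end": dm.markers["pos"],
                            "name": dm.markers["id"]})
        bed.to_csv(bed_path, sep="\t", header=False, index=False)
    if pheno_path is not None and phenotypes is not None:
        phenotypes.to_csv(pheno_path, sep="\t", index=False)
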