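"""Synthetic cattle cohorts and molecular fixtures.

Generates pedigrees, repeated binary return-to-estrus records under the
threshold liability model, deletion-CNV carrier genotypes, SNP genotypes,
SNP-array log-R-ratio/B-allele-frequency signals over a deleted interval,
and NAHR junction sequence fixtures — everything the downstream analysis
consumes, with the statistical structure it assumes, so the whole pipeline
is testable without external data.

Defaults emulate the study conditions of a national Japanese Black cattle
evaluation: five post-insemination return windows (18-29, 30-60, 61-90,
91-140, 141-285 days) with marginal return rates 23.00%, 21.97%, 16.91%,
8.47% and 3.30%; liability-scale variance components sigma2_a = 0.03,
sigma2_pe = 0.07, sigma2_e = 1; a deleted-type CNV at risk-allele frequency
0.024 with no homozygous carriers; and 63-bp homology arms flanking a
33,934-bp deletion.

All randomness flows from one seed through numpy's splittable SeedSequence,
one child stream per sub-generator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.special import ndtri
from scipy.linalg import cholesky

from .relatedness import a_matrix
from .threshold_model import VarianceComponents

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "JunctionFixture",
    "sim_pedigree",
    "sim_cnv_genotypes",
    "sim_snp_genotypes",
    "sim_breeding_values",
    "sim_records",
    "prepare_period_outcomes",
    "sim_array_signals",
    "sim_junction_fixture",
    "sim_gene_fixture",
    "make_cohort",
]

#: (first day, last day) of each return-to-estrus window, inclusive
DEFAULT_PERIODS = ((18, 29), (30, 60), (61, 90), (91, 140), (141, 285))
#: per-window return rate among cows still at risk (proportions)
DEFAULT_INCIDENCE = (0.2300, 0.2197, 0.1691, 0.0847, 0.0330)


@dataclass(frozen=True)
class SimConfig:
    """Cohort generator settings.

    The residual liability variance is fixed at 1 and the threshold at 0; mu
    absorbs location and is calibrated per window so the marginal incidence
    among at-risk cows matches ``target_incidence``.  ``fixed_effect_sd``
    is the SD of the level effects drawn for each categorical factor.
    """

    n_founders: int = 350
    founder_sires: int = 50
    n_generations: int = 1
    n_offspring_per_generation: int = 1500
    records_per_cow: int = 3
    variance_components: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(0.03, 0.07, 1.0)
    )
    n_farms: int = 10
    n_year_months: int = 12
    fixed_effect_sd: float = 0.1
    age_slope: float = 0.005      # liability units per month of age at AI
    period_definitions: tuple = DEFAULT_PERIODS
    target_incidence: tuple = DEFAULT_INCIDENCE
    cnv_risk_allele_freq: float = 0.024
    cnv_liability_effect: float = 0.5  # liability units added for carriers
    cnv_effect_period: int = 1         # index of the affected window (30-60 D)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2 or not (0 < self.founder_sires < self.n_founders):
            raise ValueError("need >= 2 founders with at least one sire and one dam")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if len(self.period_definitions) != len(self.target_incidence):
            raise ValueError("one target incidence per period required")
        for p in self.target_incidence:
            if not 0.0 <= p <= 1.0:
                raise ValueError("incidences must be proportions in [0, 1]")
        if not 0.0 <= self.cnv_risk_allele_freq <= 0.5:
            raise ValueError("risk-allele frequency must lie in [0, 0.5]")
        last = None
        for lo, hi in self.period_definitions:
            if lo > hi or (last is not None and lo <= last):
                raise ValueError("period day-ranges must be disjoint and ordered")
            last = hi
        if self.variance_components.sigma2_e != 1.0:
            raise ValueError("residual liability variance is fixed at 1")


@dataclass
class SyntheticCohort:
    """A simulated cohort plus the ground truth used to generate it."""

    pedigree: pd.DataFrame
    records: pd.DataFrame
    cnv_copy_number: pd.Series          # per recorded animal, in {1, 2}
    snp_genotypes: pd.DataFrame | None
    true_breeding_values: pd.Series     # liability units, all pedigree animals
    config: SimConfig

    def __post_init__(self):
        known = set(self.pedigree["animal"])
        if not set(self.records["animal"]).issubset(known):
            raise ValueError("record animal missing from pedigree")
        if (self.cnv_copy_number < 1).any():
            raise ValueError("homozygous deletion carriers are excluded by construction")


def sim_pedigree(config: SimConfig, rng=None) -> pd.DataFrame:
    """Simulate an acyclic pedigree: unrelated founders, then generations
    whose parents are sampled from the previous generation.

    Returns an animal/sire/dam/sex/generation table; unknown parents are
    ``None``.  Record-bearing cows are the females of the last generation.
    """
    rng = np.random.default_rng(config.rng_seed if rng is None else rng)
    rows = []
    sires = [f"S{i:05d}" for i in range(config.founder_sires)]
    dams = [f"D{i:05d}" for i in range(config.n_founders - config.founder_sires)]
    for s in sires:
        rows.append((s, None, None, "M", 0))
    for d in dams:
        rows.append((d, None, None, "F", 0))
    prev_m, prev_f = sires, dams
    for g in range(1, config.n_generations + 1):
        cur_m, cur_f = [], []
        # later generations stay mostly female: the cohort records cows
        n_males = max(2, config.n_offspring_per_generation // 20)
        for i in range(config.n_offspring_per_generation):
            aid = f"G{g}_{i:05d}"
            sire = prev_m[rng.integers(len(prev_m))]
            dam = prev_f[rng.integers(len(prev_f))]
            sex = "M" if i < n_males else "F"
            rows.append((aid, sire, dam, sex, g))
            (cur_m if sex == "M" else cur_f).append(aid)
        prev_m, prev_f = cur_m, cur_f
    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex", "generation"])


def record_animals(pedigree: pd.DataFrame) -> list:
    """Females of the last generation (founder females if no generations)."""
    last = pedigree["generation"].max()
    sel = pedigree[(pedigree["generation"] == last) & (pedigree["sex"] == "F")]
    return list(sel["animal"])


def sim_cnv_genotypes(freq, n, forbid_homozygotes=True, rng=None):
    """Draw per-animal deletion copy counts under Hardy-Weinberg equilibrium.

    Returns ``(copy_counts, n_redrawn)`` with copy counts in {0, 1, 2}
    (2 = non-carrier).  With ``forbid_homozygotes`` two-copy-deleted draws
    are redrawn as single-copy carriers and counted — the study population
    contained no homozygous deletion carriers.
    """
    if not 0.0 <= freq <= 0.5:
        raise ValueError("deletion is the minor allele: freq must be in [0, 0.5]")
    rng = np.random.default_rng(rng)
    del_alleles = rng.binomial(2, freq, size=n)
    n_redrawn = 0
    if forbid_homozygotes:
        n_redrawn = int((del_alleles == 2).sum())
        del_alleles = np.where(del_alleles == 2, 1, del_alleles)
        if n_redrawn:
            warnings.warn(
                f"{n_redrawn} homozygous-deletion draws redrawn as carriers",
                stacklevel=2,
            )
    return 2 - del_alleles, n_redrawn


def sim_snp_genotypes(animal_ids, n_markers, rng=None, maf_range=(0.05, 0.5)) -> pd.DataFrame:
    """Independent HWE SNP dosages in {0, 1, 2} (no linkage, no pedigree LD)."""
    rng = np.random.default_rng(rng)
    p = rng.uniform(*maf_range, size=n_markers)
    X = rng.binomial(2, p, size=(len(animal_ids), n_markers))
    return pd.DataFrame(
        X, index=list(animal_ids), columns=[f"snp{j:05d}" for j in range(n_markers)]
    )


def sim_breeding_values(pedigree: pd.DataFrame, sigma2_a: float, rng=None) -> pd.Series:
    """Draw additive genetic values a ~ N(0, A sigma2_a) for every animal."""
    rng = np.random.default_rng(rng)
    ids = list(pedigree["animal"])
    if sigma2_a == 0.0:
        return pd.Series(np.zeros(len(ids)), index=ids)
    founders_only = pedigree["sire"].isna().all() and pedigree["dam"].isna().all()
    z = rng.standard_normal(len(ids))
    if founders_only:
        a = np.sqrt(sigma2_a) * z
    else:
        A = a_matrix(pedigree[["animal", "sire", "dam"]]).values
        L = cholesky(A + 1e-10 * np.eye(len(ids)), lower=True)
        a = np.sqrt(sigma2_a) * (L @ z)
    return pd.Series(a, index=ids)


def _calibrated_mu(config: SimConfig) -> np.ndarray:
    """Per-period intercept so P(U > 0) equals the target incidence.

    The calibration folds every variance source into the marginal liability
    SD: genetic, permanent environmental, residual, the factor-level effects
    and the age covariate (age SD from the parity spacing and within-parity
    jitter used by ``sim_records``).
    """
    vc = config.variance_components
    age_var = (12.0 ** 2) * (config.records_per_cow ** 2 - 1) / 12.0 + 3.0
    var_fixed = 3 * config.fixed_effect_sd ** 2 + config.age_slope ** 2 * age_var
    sd_tot = np.sqrt(vc.sigma2_p + var_fixed)
    targets = np.asarray(config.target_incidence, dtype=float)
    mu = np.where(targets <= 0.0, -np.inf, -sd_tot * ndtri(1.0 - targets))
    return mu


def sim_records(
    pedigree: pd.DataFrame,
    config: SimConfig,
    rng=None,
    carriers=None,
    breeding_values: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate repeated AI opportunities with liability-driven return days.

    Each cow gets ``records_per_cow`` opportunities (one per parity).  For an
    opportunity the liability of window k is assembled exactly per the model
    (mu_k + parity + farm + year-month + b*age + a + pe [+ CNV effect] + e,
    residual fresh per window); the first window whose liability exceeds the
    threshold sets the return day (uniform within the window) and the cow
    leaves the risk set of later windows for that opportunity.  Cows that
    never return get no return day (0 in every window's dataset).

    Returns ``(records, breeding_values)``; records carry animal, parity,
    farm, ym, age and ``return_day`` (NaN = no second AI).
    """
    rng = np.random.default_rng(config.rng_seed + 1 if rng is None else rng)
    vc = config.variance_components
    cows = record_animals(pedigree)
    if breeding_values is None:
        breeding_values = sim_breeding_values(pedigree, vc.sigma2_a, rng)
    a = breeding_values.reindex(cows).to_numpy()
    pe = rng.normal(0.0, np.sqrt(vc.sigma2_pe), size=len(cows))
    carrier_set = set(carriers) if carriers is not None else set()
    carrier_vec = np.array([c in carrier_set for c in cows], dtype=float)

    parity_eff = rng.normal(0.0, config.fixed_effect_sd, size=config.records_per_cow)
    farm_eff = rng.normal(0.0, config.fixed_effect_sd, size=config.n_farms)
    ym_eff = rng.normal(0.0, config.fixed_effect_sd, size=config.n_year_months)
    farm_of_cow = rng.integers(config.n_farms, size=len(cows))
    mu = _calibrated_mu(config)
    mean_age = 24.0 + 12.0 * (config.records_per_cow - 1) / 2.0

    periods = config.period_definitions
    rows = []
    for opp in range(config.records_per_cow):
        ym = rng.integers(config.n_year_months, size=len(cows))
        age = 24.0 + 12.0 * opp + rng.uniform(-3.0, 3.0, size=len(cows))
        base = (
            parity_eff[opp]
            + farm_eff[farm_of_cow]
            + ym_eff[ym]
            + config.age_slope * (age - mean_age)
            + a
            + pe
        )
        return_day = np.full(len(cows), np.nan)
        at_risk = np.ones(len(cows), dtype=bool)
        for k, (lo, hi) in enumerate(periods):
            e = rng.standard_normal(len(cows))
            u = mu[k] + base + e
            if k == config.cnv_effect_period:
                u = u + config.cnv_liability_effect * carrier_vec
            hit = at_risk & (u > 0.0)
            if hit.any():
                return_day[hit] = rng.integers(lo, hi + 1, size=int(hit.sum()))
            at_risk &= ~hit
        for i, cow in enumerate(cows):
            rows.append(
                (cow, opp + 1, f"F{farm_of_cow[i]:02d}", f"YM{ym[i]:02d}",
                 age[i], return_day[i])
            )
    records = pd.DataFrame(
        rows, columns=["animal", "parity", "farm", "ym", "age", "return_day"]
    )
    return records, breeding_values


def prepare_period_outcomes(records: pd.DataFrame, periods=DEFAULT_PERIODS) -> dict:
    """Per-window binary datasets with sequential risk-set exclusion.

    For window k the outcome is 1 if the second AI day falls in the window;
    records whose return fell in an earlier window are excluded from window
    k's risk set; records with no second AI are 0 everywhere.
    """
    day = records["return_day"].to_numpy(dtype=float)
    if (day[np.isfinite(day)] < 0).any():
        raise ValueError("negative return day")
    out = {}
    excluded = np.zeros(len(records), dtype=bool)
    for lo, hi in periods:
        in_window = np.isfinite(day) & (day >= lo) & (day <= hi)
        keep = ~excluded
        df = records.loc[keep, ["animal", "parity", "farm", "ym", "age"]].copy()
        df["y"] = in_window[keep].astype(int)
        out[f"{lo}-{hi}"] = df.reset_index(drop=True)
        excluded |= in_window
    return out


def sim_array_signals(
    deleted_interval,
    carriers,
    animal_ids,
    marker_positions,
    rng=None,
    one_copy_shift=-0.45,
    lrr_sd=0.2,
    baf_sd=0.03,
) -> pd.DataFrame:
    """SNP-array log-R-ratio and B-allele-frequency over a deleted interval.

    Non-carrier LRR is centered at 0 everywhere; carriers are shifted by
    ``one_copy_shift`` (default -0.45, a common single-copy array response)
    at markers inside the deletion only.  Carrier BAF inside the deletion
    has no heterozygous band (one chromosome left).
    """
    rng = np.random.default_rng(rng)
    start, end = deleted_interval
    pos = np.asarray(marker_positions)
    inside = (pos >= start) & (pos <= end)
    if not inside.any():
        warnings.warn("no markers inside the deleted interval", stacklevel=2)
    carrier_set = set(carriers)
    frames = []
    for animal in animal_ids:
        is_carrier = animal in carrier_set
        lrr = rng.normal(0.0, lrr_sd, size=len(pos))
        if is_carrier:
            lrr[inside] += one_copy_shift
        geno = rng.binomial(2, 0.5, size=len(pos))
        if is_carrier:
            # hemizygous inside the deletion: a single allele, no hets
            geno_in = rng.binomial(1, 0.5, size=int(inside.sum())) * 2
            geno = np.where(inside, -1, geno)
            geno[inside] = geno_in
        baf = np.clip(geno / 2.0 + rng.normal(0.0, baf_sd, size=len(pos)), 0.0, 1.0)
        frames.append(
            pd.DataFrame(
                {"animal": animal, "pos": pos, "lrr": lrr, "baf": baf,
                 "carrier": is_carrier}
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class JunctionFixture:
    """Reference + deleted-allele (junction) sequence with ground truth."""

    reference: str
    junction_read: str
    truth: dict

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        SeqIO.write(
            [SeqRecord(Seq(self.reference), id="ref", description="wild-type locus")],
            d / "reference.fasta", "fasta",
        )
        SeqIO.write(
            [SeqRecord(Seq(self.junction_read), id="junction",
                       description="deleted allele")],
            d / "junction.fasta", "fasta",
        )
        (d / "truth.json").write_text(json.dumps(self.truth, indent=2))


_BASES = np.array(list("ACGT"))


def sim_junction_fixture(
    arm_length=63, deletion_length=33_934, flank=500, rng=None, anchor_min=20
) -> JunctionFixture:
    """Build an NAHR deletion fixture.

    The reference is ``flank | arm | interior | arm | flank``: two identical
    same-orientation homology-arm copies separated by the deletion interior.
    The junction read is the deleted allele (left flank + one arm copy +
    right flank).  ``deletion_length`` follows the end-minus-end difference
    convention, so the interior is ``deletion_length - arm_length`` bases.
    The first/last interior bases are forced to differ from the bases that
    would extend the homology by coincidence, so the ambiguity interval
    equals the arm length exactly.  Coordinates in the truth record are
    1-based inclusive.
    """
    if arm_length < 0:
        raise ValueError("arm_length must be >= 0")
    if deletion_length <= arm_length:
        raise ValueError("deletion_length must exceed arm_length")
    if flank < anchor_min:
        raise ValueError(f"flank must be >= the read-anchor minimum ({anchor_min})")
    rng = np.random.default_rng(rng)
    interior_len = deletion_length - arm_length

    def rand_seq(n):
        return "".join(_BASES[rng.integers(4, size=n)])

    left = rand_seq(flank)
    right = rand_seq(flank)
    arm = rand_seq(arm_length)
    interior = list(rand_seq(interior_len))
    # block coincidental homology extension across the breakpoint
    if interior_len > 0:
        while interior[0] == right[0]:
            interior[0] = str(_BASES[rng.integers(4)])
        while interior[-1] == left[-1]:
            interior[-1] = str(_BASES[rng.integers(4)])
    interior = "".join(interior)

    reference = left + arm + interior + arm + right
    junction = left + arm + right
    la_start = flank + 1
    la_end = flank + arm_length
    ra_start = flank + arm_length + interior_len + 1
    ra_end = ra_start + arm_length - 1
    truth = {
        "arm_length": arm_length,
        "left_arm": [la_start, la_end] if arm_length else None,
        "right_arm": [ra_start, ra_end] if arm_length else None,
        "deletion_length": deletion_length,
        "ambiguity": arm_length,
        "flank": flank,
    }
    return JunctionFixture(reference, junction, truth)


def sim_gene_fixture(rng=None):
    """An eight-exon gene whose deletion consequences mirror the study gene.

    Wild-type protein 324 aa (975-nt CDS including the stop codon).  Exons
    2-6 carry 462 coding nt, so deleting them leaves a 513-nt in-frame CDS
    (170 aa); retaining the 90-bp intron between exons 7 and 8 adds 30 aa
    (200 aa).  Returns ``(gene, deletion_interval, retained_intron)`` where
    the gene carries a generated chromosome sequence so consequences can be
    verified by translation.

    The fixture is synthetic: exon sizes are chosen to reproduce the
    arithmetic above, not the real gene's coordinates.
    """
    from .structvar import GeneModel

    rng = np.random.default_rng(rng)
    coding = [75, 90, 96, 93, 90, 93, 150, 288]  # per exon; sums to 975
    intron_lengths = [200, 150, 150, 150, 150, 200, 90]  # intron 7-8 is 90 bp
    upstream = 100
    pos = upstream + 1
    exons = []
    for i, clen in enumerate(coding):
        exons.append((pos, pos + clen - 1))
        pos += clen
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    gene_end = exons[-1][1]
    seq_len = gene_end + 100

    seq = _BASES[rng.integers(4, size=seq_len)]
    cds_start, cds_end = exons[0][0], exons[-1][1]
    # lay down codons exon by exon so there is no premature stop in frame
    codon_bank = [c for c in (
        "GCT GGT CTT AAA GAT GAA TTT CAT ATT ATG AAT CCT CAA CGT TCT ACT "
        "GTT TGG TAT TGC".split()
    )]
    coding_positions = []
    for (s, e) in exons:
        coding_positions.extend(range(s - 1, e))
    n_codons = len(coding_positions) // 3
    body = []
    body.append("ATG")
    for j in range(1, n_codons - 1):
        body.append(codon_bank[int(rng.integers(len(codon_bank)))])
    body.append("TAA")
    cds_seq = "".join(body)
    for p, base in zip(coding_positions, cds_seq):
        seq[p] = base
    # retained intron between exons 7 and 8 must stay stop-free in frame:
    # exon 7 ends in-frame (75+462-462... cumulative coding to exon 7 = 687,
    # divisible by 3), so fill the intron with a stop-free codon run
    i7 = (exons[6][1], exons[7][0])  # 1-based: intron spans i7[0]+1 .. i7[1]-1
    intron_span = range(i7[0], i7[1] - 1)
    filler = ("GCA" * 30)[: len(intron_span)]
    for p, base in zip(intron_span, filler):
        seq[p] = base

    gene = GeneModel(
        gene_id="geneA",
        strand="+",
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        sequence="".join(seq),
    )
    # deletion fully covering exons 2..6 but not exons 1 or 7
    deletion = (exons[1][0] - 50, exons[5][1] + 50)
    retained_intron = (exons[6][1] + 1, exons[7][0] - 1)
    assert retained_intron[1] - retained_intron[0] + 1 == 90
    return gene, deletion, retained_intron


def make_cohort(config: SimConfig) -> SyntheticCohort:
    """Simulate a full cohort: pedigree, CNV carriers, records, SNPs."""
    streams = np.random.SeedSequence(config.rng_seed).spawn(5)
    ped_rng, cnv_rng, rec_rng, snp_rng, _ = (np.random.default_rng(s) for s in streams)
    pedigree = sim_pedigree(config, ped_rng)
    cows = record_animals(pedigree)
    copies, _ = sim_cnv_genotypes(
        config.cnv_risk_allele_freq, len(cows), forbid_homozygotes=True, rng=cnv_rng
    )
    cnv = pd.Series(copies, index=cows)
    carriers = list(cnv.index[cnv == 1])
    records, bv = sim_records(pedigree, config, rec_rng, carriers=carriers)
    snps = sim_snp_genotypes(cows, 500, snp_rng)
    return SyntheticCohort(pedigree, records, cnv, snps, bv, config)
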