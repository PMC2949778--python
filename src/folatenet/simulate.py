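"""Synthetic case-control cohort generator.

Emulates the statistical structure the analysis assumes: per-group genotype
marginals drawn directly at the genotype level (no Hardy-Weinberg
assumption — the study reports genotype counts, not allele counts),
group-specific BNMN values from a normal truncated at zero, optional
haplotype-level couplings between locus pairs (linkage disequilibrium,
modelled as random union of two haplotypes per subject), and optional
uninformative noise loci with group-independent genotype frequencies.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .cohort import GROUP_CASE, GROUP_CONTROL, GROUPS, CohortDataset, GroupSummary, SubjectRecord
from .loci import CANONICAL_LOCI, LocusSchema, noise_locus_schema

# Published per-group genotype counts and BNMN moments of the study cohort
# (29 case mothers / 32 controls); used to calibrate the generator.
STUDY_GROUP_SIZES = {GROUP_CASE: 29, GROUP_CONTROL: 32}
STUDY_GENOTYPE_COUNTS: dict[tuple[str, str], tuple[int, int, int]] = {
    (GROUP_CASE, "MTHFR677"): (5, 19, 5),
    (GROUP_CONTROL, "MTHFR677"): (11, 17, 4),
    (GROUP_CASE, "MTHFR1298"): (14, 15, 0),
    (GROUP_CONTROL, "MTHFR1298"): (13, 19, 0),
    (GROUP_CASE, "MTRR66"): (9, 14, 6),
    (GROUP_CONTROL, "MTRR66"): (12, 14, 6),
    (GROUP_CASE, "MTR2756"): (20, 9, 0),
    (GROUP_CONTROL, "MTR2756"): (24, 6, 2),
    (GROUP_CASE, "RFC1_80"): (12, 16, 1),
    (GROUP_CONTROL, "RFC1_80"): (10, 12, 10),
    (GROUP_CASE, "TYMS_28bp"): (5, 19, 5),
    (GROUP_CONTROL, "TYMS_28bp"): (6, 14, 12),
    (GROUP_CASE, "TYMS_6bp"): (5, 21, 3),
    (GROUP_CONTROL, "TYMS_6bp"): (8, 19, 5),
}
STUDY_BNMN = {GROUP_CASE: (16.5, 7.6), GROUP_CONTROL: (9.3, 3.1)}


def study_reference_summary() -> GroupSummary:
    """The published cohort summary as a :class:`GroupSummary`."""
    return GroupSummary(
        n=dict(STUDY_GROUP_SIZES),
        genotype_counts=dict(STUDY_GENOTYPE_COUNTS),
        bnmn_mean={g: STUDY_BNMN[g][0] for g in GROUPS},
        bnmn_sd={g: STUDY_BNMN[g][1] for g in GROUPS},
    )


@dataclass
class HaplotypeCoupling:
    """Haplotype-level linkage between two biallelic loci.

    ``haplotype_freqs[group]`` is a 2x2 array over (allele at locus_a,
    allele at locus_b), indexed 0 = major, 1 = minor; a subject's genotype
    pair is the random union of two independent haplotype draws.
    """

    locus_a: str
    locus_b: str
    haplotype_freqs: dict[str, np.ndarray]

    def validate(self) -> None:
        for g, h in self.haplotype_freqs.items():
            h = np.asarray(h, dtype=float)
            if h.shape != (2, 2):
                raise ValueError(f"{g}: haplotype table must be 2x2")
            if (h < -1e-12).any():
                raise ValueError(f"{g}: negative haplotype frequency in {self.locus_a}/{self.locus_b}")
            if abs(h.sum() - 1.0) > 1e-9:
                raise ValueError(f"{g}: haplotype frequencies must sum to 1")


@dataclass
class GeneratorConfig:
    """Everything needed to draw a cohort; same seed, same cohort."""

    n_mds: int
    n_ctrl: int
    genotype_probs: dict[tuple[str, str], tuple[float, float, float]]
    bnmn_params: dict[str, tuple[float, float]]
    couplings: list[HaplotypeCoupling] = field(default_factory=list)
    loci: tuple[LocusSchema, ...] = CANONICAL_LOCI
    seed: int = 0

    def validate(self) -> None:
        if self.n_mds < 1 or self.n_ctrl < 1:
            raise ValueError("both group sizes must be >= 1")
        for g in GROUPS:
            for schema in self.loci:
                p = self.genotype_probs.get((g, schema.locus_name))
                if p is None:
                    raise ValueError(f"missing genotype probabilities for {g}/{schema.locus_name}")
                if min(p) < 0 or abs(sum(p) - 1.0) > 1e-9:
                    raise ValueError(
                        f"{g}/{schema.locus_name}: probabilities must be >=0 and sum to 1, got {p}"
                    )
            mean, sd = self.bnmn_params[g]
            if sd <= 0:
                raise ValueError(f"{g}: BNMN sd must be > 0")
        coupled = set()
        for c in self.couplings:
            c.validate()
            for locus in (c.locus_a, c.locus_b):
                if locus not in {s.locus_name for s in self.loci}:
                    raise ValueError(f"coupling references unknown locus {locus}")
                if locus in coupled:
                    raise ValueError(f"locus {locus} appears in more than one coupling")
                coupled.add(locus)
            for g in GROUPS:
                ha = minor_allele_freq(self.genotype_probs[(g, c.locus_a)])
                hb = minor_allele_freq(self.genotype_probs[(g, c.locus_b)])
                h = np.asarray(c.haplotype_freqs[g], dtype=float)
                if abs(h[1, :].sum() - ha) > 1e-6 or abs(h[:, 1].sum() - hb) > 1e-6:
                    raise ValueError(
                        f"{g}: haplotype table of {c.locus_a}/{c.locus_b} does not match "
                        "the loci's allele marginals"
                    )

    def schema(self, name: str) -> LocusSchema:
        for s in self.loci:
            if s.locus_name == name:
                return s
        raise KeyError(name)

    def to_json(self) -> str:
        d = {
            "n_mds": self.n_mds,
            "n_ctrl": self.n_ctrl,
            "seed": self.seed,
            "bnmn_params": {g: list(v) for g, v in self.bnmn_params.items()},
            "genotype_probs": {f"{g}|{l}": list(p) for (g, l), p in self.genotype_probs.items()},
            "loci": [
                {"name": s.locus_name, "labels": list(s.genotype_labels), "alleles": list(s.alleles)}
                for s in self.loci
            ],
            "couplings": [
                {
                    "locus_a": c.locus_a,
                    "locus_b": c.locus_b,
                    "haplotype_freqs": {g: np.asarray(h).tolist() for g, h in c.haplotype_freqs.items()},
                }
                for c in self.couplings
            ],
        }
        return json.dumps(d, indent=2)


def minor_allele_freq(genotype_probs) -> float:
    """Minor-allele frequency implied by (major-hom, het, minor-hom) probs."""
    p0, p1, p2 = genotype_probs
    return p1 / 2.0 + p2


def calibrate_from_summary(gs: GroupSummary, seed: int = 0) -> GeneratorConfig:
    """Turn observed per-group counts and BNMN moments into a generator.

    Genotype probabilities are count/n per group and locus; BNMN parameters
    are the printed mean/SD. No couplings are added here.
    """
    probs = {}
    for (g, locus), counts in gs.genotype_counts.items():
        n = gs.n[g]
        if sum(counts) != n:
            raise ValueError(f"{g}/{locus}: counts {counts} do not sum to n={n}")
        probs[(g, locus)] = tuple(c / n for c in counts)
    return GeneratorConfig(
        n_mds=gs.n[GROUP_CASE],
        n_ctrl=gs.n[GROUP_CONTROL],
        genotype_probs=probs,
        bnmn_params={g: (gs.bnmn_mean[g], gs.bnmn_sd[g]) for g in GROUPS},
        loci=gs.loci,
        seed=seed,
    )


def plant_haplotype_coupling(
    cfg: GeneratorConfig,
    locus_a: str,
    locus_b: str,
    rare_haplotype: tuple[str, str],
    freq: float = 0.0,
) -> GeneratorConfig:
    """Couple two loci so the named haplotype has frequency ``freq``.

    The remaining three haplotype frequencies are set to preserve both
    loci's allele marginals exactly. Infeasible (marginal, freq)
    combinations are rejected with the violated constraint.
    """
    cfg = copy.deepcopy(cfg)
    sa, sb = cfg.schema(locus_a), cfg.schema(locus_b)
    if locus_a == locus_b:
        raise ValueError("coupling needs two distinct loci")
    ia = sa.alleles.index(rare_haplotype[0])
    ib = sb.alleles.index(rare_haplotype[1])
    tables = {}
    for g in GROUPS:
        pa = minor_allele_freq(cfg.genotype_probs[(g, locus_a)])  # minor at a
        pb = minor_allele_freq(cfg.genotype_probs[(g, locus_b)])
        fa = pa if ia == 1 else 1.0 - pa  # freq of the named allele at a
        fb = pb if ib == 1 else 1.0 - pb
        lo, hi = max(0.0, fa + fb - 1.0), min(fa, fb)
        if not (lo - 1e-12 <= freq <= hi + 1e-12):
            raise ValueError(
                f"{g}: haplotype {rare_haplotype} frequency {freq} infeasible; "
                f"allele marginals ({fa:.4f}, {fb:.4f}) require it in [{lo:.4f}, {hi:.4f}]"
            )
        h = np.empty((2, 2))
        h[ia, ib] = freq
        h[ia, 1 - ib] = fa - freq
        h[1 - ia, ib] = fb - freq
        h[1 - ia, 1 - ib] = 1.0 - fa - fb + freq
        tables[g] = h
    cfg.couplings.append(HaplotypeCoupling(locus_a, locus_b, tables))
    cfg.validate()
    return cfg


def independence_coupling(cfg: GeneratorConfig, locus_a: str, locus_b: str) -> GeneratorConfig:
    """Couple two loci at the independence product (no linkage)."""
    cfg = copy.deepcopy(cfg)
    tables = {}
    for g in GROUPS:
        pa = minor_allele_freq(cfg.genotype_probs[(g, locus_a)])
        pb = minor_allele_freq(cfg.genotype_probs[(g, locus_b)])
        a = np.array([1.0 - pa, pa])
        b = np.array([1.0 - pb, pb])
        tables[g] = np.outer(a, b)
    cfg.couplings.append(HaplotypeCoupling(locus_a, locus_b, tables))
    cfg.validate()
    return cfg


def append_noise_loci(cfg: GeneratorConfig, k: int, seed: int = 0) -> GeneratorConfig:
    """Add ``k`` uninformative loci with group-independent genotype probs.

    Class probabilities are drawn once (flat Dirichlet, given ``seed``) and
    fixed thereafter; by construction noise loci carry no association with
    the case/control label.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return cfg
    cfg = copy.deepcopy(cfg)
    rng = np.random.default_rng(seed)
    existing = sum(1 for s in cfg.loci if s.locus_name.startswith("NOISE"))
    new = []
    for i in range(k):
        schema = noise_locus_schema(existing + i)
        p = tuple(rng.dirichlet(np.ones(3)))
        new.append(schema)
        for g in GROUPS:
            cfg.genotype_probs[(g, schema.locus_name)] = p
    cfg.loci = tuple(cfg.loci) + tuple(new)
    cfg.validate()
    return cfg


def _genotype_from_haplotypes(h1: int, h2: int, schema: LocusSchema) -> str:
    """Map two allele draws (0 major / 1 minor) to the genotype label."""
    return schema.genotype_labels[h1 + h2]


def generate_cohort(cfg: GeneratorConfig) -> CohortDataset:
    """Draw a cohort; deterministic given the config (including its seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    coupled_loci = {}
    for c in cfg.couplings:
        coupled_loci[c.locus_a] = (c, 0)
        coupled_loci[c.locus_b] = (c, 1)

    records = []
    for group, n, prefix in (
        (GROUP_CASE, cfg.n_mds, "MDS"),
        (GROUP_CONTROL, cfg.n_ctrl, "CTRL"),
    ):
        mean, sd = cfg.bnmn_params[group]
        a = (0.0 - mean) / sd  # truncate the normal at zero
        bnmn = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
        # draw coupled pairs as two haplotypes per subject
        pair_calls: dict[str, list[str]] = {}
        for c in cfg.couplings:
            h = np.asarray(c.haplotype_freqs[group], dtype=float).ravel()
            draws = rng.choice(4, size=(n, 2), p=h / h.sum())
            a_alleles = draws // 2
            b_alleles = draws % 2
            sa, sb = cfg.schema(c.locus_a), cfg.schema(c.locus_b)
            pair_calls[c.locus_a] = [
                _genotype_from_haplotypes(int(x[0]), int(x[1]), sa) for x in a_alleles
            ]
            pair_calls[c.locus_b] = [
                _genotype_from_haplotypes(int(x[0]), int(x[1]), sb) for x in b_alleles
            ]
        # uncoupled loci: genotype-level multinomial draws
        locus_calls: dict[str, list[str]] = {}
        for schema in cfg.loci:
            if schema.locus_name in coupled_loci:
                locus_calls[schema.locus_name] = pair_calls[schema.locus_name]
            else:
                p = np.array(cfg.genotype_probs[(group, schema.locus_name)])
                idx = rng.choice(3, size=n, p=p / p.sum())
                locus_calls[schema.locus_name] = [schema.genotype_labels[i] for i in idx]
        for i in range(n):
            records.append(
                SubjectRecord(
                    subject_id=f"{prefix}-{i + 1:03d}",
                    group=group,
                    bnmn=float(bnmn[i]),
                    calls={name: calls[i] for name, calls in locus_calls.items()},
                )
            )
    return CohortDataset(records, cfg.loci)


def coupled_genotype_distribution(c: HaplotypeCoupling, group: str) -> np.ndarray:
    """Exact 3x3 genotype-pair distribution implied by a coupling.

    Enumerates the 16 ordered haplotype pairs; used by the feasibility
    checks and by tests (never produces negative mass for a valid table).
    """
    h = np.asarray(c.haplotype_freqs[group], dtype=float)
    out = np.zeros((3, 3))
    for a1 in range(2):
        for b1 in range(2):
            for a2 in range(2):
                for b2 in range(2):
                    out[a1 + a2, b1 + b2] += h[a1, b1] * h[a2, b2]
    return out


def study_calibrated_config(
    seed: int = 0,
    with_ld: bool = True,
    n_noise_loci: int = 0,
    noise_seed: int | None = None,
) -> GeneratorConfig:
    """Generator calibrated to the published cohort.

    With ``with_ld`` the two linkage couplings described for this pathway
    are planted: the MTHFR 677T-1298C haplotype and the TYMS 2R-6bp(−)
    haplotype are both rare (frequency 0 here).
    """
    cfg = calibrate_from_summary(study_reference_summary(), seed=seed)
    if with_ld:
        cfg = plant_haplotype_coupling(cfg, "MTHFR677", "MTHFR1298", ("T", "C"), 0.0)
        cfg = plant_haplotype_coupling(cfg, "TYMS_28bp", "TYMS_6bp", ("2R", "-"), 0.0)
    if n_noise_loci:
        cfg = append_noise_loci(cfg, n_noise_loci, seed if noise_seed is None else noise_seed)
    return cfg
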