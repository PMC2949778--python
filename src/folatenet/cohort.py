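"""Subject-level cohort container, genotype coding, summaries and the
univariate correlation screen.

The cohort is one row per mother: case/control group (MDS = mother of a
Down-syndrome child), the lymphocyte micronucleus frequency BNMN (per mille
binucleated micronucleated cells), and one genotype call per locus. Each
locus expands to three binary indicators (major homozygote, heterozygote,
minor homozygote); BNMN is min-max scaled to [0, 1] so every network input
is bounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loci import CANONICAL_LOCI, LocusSchema

GROUP_CASE = "MDS"
GROUP_CONTROL = "control"
GROUPS = (GROUP_CASE, GROUP_CONTROL)

BNMN_FEATURE = "BNMN"


def feature_name(locus: str, label: str) -> str:
    return f"{locus} {label}"


@dataclass(frozen=True)
class SubjectRecord:
    """One mother: id, case/control group, BNMN per-mille, genotype calls."""

    subject_id: str
    group: str
    bnmn: float
    calls: dict[str, str]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.subject_id}: group must be one of {GROUPS}, got {self.group!r}")
        if not np.isfinite(self.bnmn) or self.bnmn < 0:
            raise ValueError(f"{self.subject_id}: BNMN must be a finite non-negative per-mille value")


@dataclass
class CohortDataset:
    """A list of subject records plus the locus schemas they are called on."""

    records: list[SubjectRecord]
    loci: tuple[LocusSchema, ...] = CANONICAL_LOCI

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")
        for r in self.records:
            for schema in self.loci:
                call = r.calls.get(schema.locus_name)
                if call is None:
                    raise ValueError(f"{r.subject_id}: missing call for locus {schema.locus_name}")
                schema.class_index(call)  # raises on unknown label

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.records) if r.group == group], dtype=int)

    def require_both_groups(self) -> None:
        for g in GROUPS:
            if len(self.group_indices(g)) == 0:
                raise ValueError(f"group {g!r} is empty; analysis needs both groups")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"subject_id": r.subject_id, "group": r.group, "BNMN": r.bnmn}
            for schema in self.loci:
                row[schema.locus_name] = r.calls[schema.locus_name]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class EncodedMatrix:
    """The network-ready design: 3 indicators per locus + scaled BNMN.

    ``y`` codes the case group (MDS) as 1 and controls as 0, so downstream
    sensitivity is recall on MDS. ``bnmn_scaling`` stores the (min, max)
    used, for reuse on held-out data.
    """

    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    bnmn_scaling: tuple[float, float]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match X's column count")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.min(initial=0.0) < 0 or self.X.max(initial=0.0) > 1:
            raise ValueError("encoded features must lie in [0, 1]")
        if not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ValueError("y must be binary")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def columns(self, names: list[str]) -> np.ndarray:
        idx = [self.feature_names.index(n) for n in names]
        return self.X[:, idx]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids or range(len(df)))
        df["target"] = self.y.astype(int)
        df.to_csv(path, sep="\t", index=False)


def encode_genotype(call: str, schema: LocusSchema) -> tuple[int, int, int]:
    """Binary expansion of one genotype call into its three class indicators.

    Exactly one indicator is 1, at the index of the call in the
    (major homozygote, heterozygote, minor homozygote) ordering.
    """
    triple = [0, 0, 0]
    triple[schema.class_index(call)] = 1
    return tuple(triple)


def encode_cohort(ds: CohortDataset, bnmn_scaling: tuple[float, float] | None = None) -> EncodedMatrix:
    """Expand a cohort into the bounded [0, 1] design matrix.

    Per locus, the three one-hot class indicators; then BNMN min-max scaled
    over the cohort (or with a supplied (min, max), values clipped into
    [0, 1]). A degenerate BNMN range maps to a constant 0.5 with a warning.
    """
    names: list[str] = []
    for schema in ds.loci:
        names.extend(feature_name(schema.locus_name, lab) for lab in schema.genotype_labels)
    names.append(BNMN_FEATURE)

    bnmn = np.array([r.bnmn for r in ds.records], dtype=float)
    if bnmn_scaling is None:
        lo, hi = (float(bnmn.min()), float(bnmn.max())) if len(bnmn) else (0.0, 0.0)
    else:
        lo, hi = map(float, bnmn_scaling)
    if hi - lo <= 0:
        warnings.warn("degenerate BNMN range; scaled BNMN column set to 0.5", stacklevel=2)
        scaled = np.full_like(bnmn, 0.5)
    else:
        scaled = np.clip((bnmn - lo) / (hi - lo), 0.0, 1.0)

    X = np.zeros((len(ds.records), len(names)))
    for i, r in enumerate(ds.records):
        col = 0
        for schema in ds.loci:
            X[i, col:col + 3] = encode_genotype(r.calls[schema.locus_name], schema)
            col += 3
        X[i, col] = scaled[i]
    y = np.array([1.0 if r.group == GROUP_CASE else 0.0 for r in ds.records])
    return EncodedMatrix(names, X, y, (lo, hi), subject_ids=ds.subject_ids)


def _parse_bnmn(raw, line_no: int) -> float:
    s = str(raw).strip().replace(",", ".")
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"line {line_no}: unparseable BNMN value {raw!r}") from None


def read_cohort(
    path,
    loci: tuple[LocusSchema, ...] = CANONICAL_LOCI,
    column_map: dict[str, str] | None = None,
) -> CohortDataset:
    """Read a subject-level CSV (header row; decimal comma or point in BNMN).

    ``column_map`` maps the logical names ("subject_id", "group", "BNMN",
    locus names) to whatever the file's header actually calls them, to
    absorb unknown header spellings.
    """
    df = pd.read_csv(path, dtype=str, sep=",")
    cmap = {k: k for k in ["subject_id", "group", "BNMN"] + [s.locus_name for s in loci]}
    if column_map:
        cmap.update(column_map)
    # subject_id is optional in input files; ids are synthesized if absent
    required = [cmap[k] for k in ["group", "BNMN"] + [s.locus_name for s in loci]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) in {path}: {missing}")

    records = []
    has_ids = cmap["subject_id"] in df.columns
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        sid = str(row[cmap["subject_id"]]) if has_ids else f"S{i + 1:03d}"
        group = str(row[cmap["group"]]).strip()
        if group not in GROUPS:
            raise ValueError(f"line {line_no}: unknown group label {group!r}")
        bnmn = _parse_bnmn(row[cmap["BNMN"]], line_no)
        calls = {}
        for schema in loci:
            call = str(row[cmap[schema.locus_name]]).strip()
            if call not in schema.genotype_labels:
                raise ValueError(
                    f"line {line_no}: unknown genotype label {call!r} for locus {schema.locus_name}"
                )
            calls[schema.locus_name] = call
        records.append(SubjectRecord(sid, group, bnmn, calls))
    return CohortDataset(records, loci)


def write_cohort(ds: CohortDataset, path) -> None:
    """Write the cohort as the same CSV schema ``read_cohort`` accepts."""
    ds.to_dataframe().to_csv(path, index=False)


@dataclass
class GroupSummary:
    """Per-group sample sizes, genotype-class counts and BNMN moments."""

    n: dict[str, int]
    genotype_counts: dict[tuple[str, str], tuple[int, int, int]]  # (group, locus) -> counts
    bnmn_mean: dict[str, float]
    bnmn_sd: dict[str, float]
    loci: tuple[LocusSchema, ...] = CANONICAL_LOCI
    degenerate_sd: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for (g, locus), counts in self.genotype_counts.items():
            if sum(counts) != self.n[g]:
                raise ValueError(
                    f"{g}/{locus}: genotype counts {counts} sum to {sum(counts)}, expected n={self.n[g]}"
                )
        for g, sd in self.bnmn_sd.items():
            if sd < 0:
                raise ValueError(f"{g}: negative BNMN sd")


def summarize_cohort(ds: CohortDataset) -> GroupSummary:
    """Per-group genotype-class counts and BNMN mean ± SD (n−1 denominator)."""
    ds.require_both_groups()
    n, counts, means, sds = {}, {}, {}, {}
    degenerate = set()
    for g in GROUPS:
        idx = ds.group_indices(g)
        n[g] = len(idx)
        bnmn = np.array([ds.records[i].bnmn for i in idx])
        means[g] = float(bnmn.mean())
        if len(idx) < 2:
            sds[g] = 0.0
            degenerate.add(g)
        else:
            sds[g] = float(bnmn.std(ddof=1))
        for schema in ds.loci:
            c = [0, 0, 0]
            for i in idx:
                c[schema.class_index(ds.records[i].calls[schema.locus_name])] += 1
            counts[(g, schema.locus_name)] = tuple(c)
    return GroupSummary(n, counts, means, sds, ds.loci, degenerate)


def correlation_screen(em: EncodedMatrix) -> list[tuple[str, float]]:
    """Pearson correlation of every feature with the case/control target.

    For the continuous BNMN column this equals the point-biserial
    correlation. Zero-variance features are reported as r = 0 (flagged with
    a warning). Sorted by |r| descending.
    """
    if len(set(np.unique(em.y))) < 2:
        raise ValueError("correlation screen needs both classes present")
    y = em.y - em.y.mean()
    sy = float(np.sqrt((y ** 2).sum()))
    out = []
    for j, name in enumerate(em.feature_names):
        x = em.X[:, j] - em.X[:, j].mean()
        sx = float(np.sqrt((x ** 2).sum()))
        if sx == 0.0:
            warnings.warn(f"zero-variance feature {name!r}; r reported as 0", stacklevel=2)
            out.append((name, 0.0))
        else:
            out.append((name, float((x @ y) / (sx * sy))))
    out.sort(key=lambda t: (-abs(t[1]), t[0]))
    return out
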