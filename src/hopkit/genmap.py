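"""Linkage-map summaries, sex-association scanning, and putative
sex-chromosome nomination.

Hop is dioecious with an XX/XY sex system; in a bi-parental mapping
population, markers on the X chromosome co-segregate with offspring sex.
Scanning every marker's genotype × sex contingency table therefore
nominates the scaffold where significant markers pile up as the putative X.
Genotypes use the {A, H, B} coding of a bi-parental cross (homozygous
parent-1, heterozygous, homozygous parent-2), with '-' for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "SexScanResult",
    "map_summary",
    "sex_association_scan",
    "putative_sex_chromosome",
    "segregation_qc",
]

GENOTYPE_CODES = ("A", "H", "B")
MISSING = "-"


@dataclass
class GeneticMap:
    """groups: group id -> ordered list of (marker id, position cM)."""

    groups: dict[str, list[tuple[str, float]]]

    def __post_init__(self) -> None:
        for gid, markers in self.groups.items():
            if not markers:
                raise ValueError(f"group {gid} has no markers")
            pos = [p for _, p in markers]
            if any(p < 0 for p in pos):
                raise ValueError(f"group {gid}: negative cM position")
            if any(b < a for a, b in zip(pos, pos[1:])):
                raise ValueError(f"group {gid}: positions decrease")


@dataclass
class GenotypeMatrix:
    """markers × individuals genotype codes with per-individual sex and
    per-marker scaffold assignment."""

    marker_ids: list[str]
    individual_ids: list[str]
    genotypes: np.ndarray  # dtype '<U1', shape (n_markers, n_individuals)
    sex: list[str]  # 'female' / 'male' per individual
    scaffolds: list[str]  # per marker

    def __post_init__(self) -> None:
        n_m, n_i = self.genotypes.shape
        if len(self.marker_ids) != n_m or len(self.scaffolds) != n_m:
            raise ValueError("marker dimension mismatch")
        if len(self.individual_ids) != n_i or len(self.sex) != n_i:
            raise ValueError("individual dimension mismatch")
        bad = set(np.unique(self.genotypes)) - set(GENOTYPE_CODES) - {MISSING}
        if bad:
            raise ValueError(f"unknown genotype codes: {bad}")
        if set(self.sex) - {"female", "male"}:
            raise ValueError("sex must be 'female' or 'male'")


@dataclass
class SexScanResult:
    table: pd.DataFrame  # marker, scaffold, statistic, df, p, significant
    alpha: float
    adjusted: bool
    significant_markers: list[str]
    per_scaffold_counts: pd.DataFrame  # scaffold, n_significant


def map_summary(gmap: GeneticMap) -> dict:
    """Marker and length summary of a genetic map.

    Definitions (stated here because denominators vary across the
    literature): group length = last - first position; total cM = sum of
    group lengths; mean gap = total cM / (n_markers - n_groups), i.e.
    within-group gaps only — the only denominator under which every counted
    gap is defined.
    """
    if not gmap.groups:
        raise ValueError("map has no groups")
    n_groups = len(gmap.groups)
    n_markers = sum(len(m) for m in gmap.groups.values())
    lengths = {
        gid: markers[-1][1] - markers[0][1]
        for gid, markers in gmap.groups.items()
    }
    total_cm = sum(lengths.values())
    n_gaps = n_markers - n_groups
    return {
        "n_groups": n_groups,
        "n_markers": n_markers,
        "total_cm": total_cm,
        "mean_markers_per_group": n_markers / n_groups,
        "mean_gap_cm": total_cm / n_gaps if n_gaps else float("nan"),
        "group_lengths_cm": lengths,
        "group_marker_counts": {
            gid: len(m) for gid, m in gmap.groups.items()
        },
        "definitions": (
            "total_cm = sum over groups of (last - first position); "
            "mean_gap_cm = total_cm / (n_markers - n_groups) "
            "(within-group gaps only)"
        ),
    }


def _marker_test(row: np.ndarray, sex: np.ndarray) -> tuple[float, int, float, bool]:
    """Chi-squared independence test of one marker's genotype classes vs
    sex. Returns (statistic, df, p, informative)."""
    keep = row != MISSING
    r, s = row[keep], sex[keep]
    classes = [g for g in GENOTYPE_CODES if np.any(r == g)]
    if len(classes) < 2:
        return 0.0, 0, 1.0, False
    table = np.array(
        [
            [np.sum((r == g) & (s == "female")), np.sum((r == g) & (s == "male"))]
            for g in classes
        ]
    )
    # drop all-zero sex columns (single-sex data already rejected upstream)
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return 0.0, 0, 1.0, False
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p), True


def sex_association_scan(
    gm: GenotypeMatrix, alpha: float = 0.05, adjust: bool = False
) -> SexScanResult:
    """Per-marker chi-squared scan of genotype × sex independence.

    Missing genotypes are excluded per marker; genotype classes absent from
    a marker are dropped with the df adjusted. Markers with a single
    observed class are uninformative (p = 1 by convention). Significance is
    raw p < alpha, or BH-adjusted q < alpha with ``adjust``.
    """
    sex = np.asarray(gm.sex)
    if np.sum(sex == "female") < 2 or np.sum(sex == "male") < 2:
        raise ValueError("need at least two individuals of each sex")
    rows = []
    for i, mid in enumerate(gm.marker_ids):
        stat, df, p, informative = _marker_test(gm.genotypes[i], sex)
        rows.append(
            {
                "marker": mid,
                "scaffold": gm.scaffolds[i],
                "statistic": stat,
                "df": df,
                "p": p,
                "informative": informative,
            }
        )
    table = pd.DataFrame(rows)
    if adjust:
        from .enrich import bh_fdr

        table["q"] = bh_fdr(table["p"].to_numpy())
        table["significant"] = table["informative"] & (table["q"] < alpha)
    else:
        table["significant"] = table["informative"] & (table["p"] < alpha)
    sig = table.loc[table["significant"], "marker"].tolist()
    counts = (
        table.loc[table["significant"]]
        .groupby("scaffold")
        .size()
        .rename("n_significant")
        .reset_index()
        .sort_values(["n_significant", "scaffold"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return SexScanResult(
        table=table,
        alpha=alpha,
        adjusted=adjust,
        significant_markers=sig,
        per_scaffold_counts=counts,
    )


@dataclass
class SexChromosomeCall:
    scaffold: str | None
    n_significant: int
    fraction_of_significant: float
    ambiguous: bool
    tied_scaffolds: list[str] = field(default_factory=list)


def putative_sex_chromosome(scan: SexScanResult) -> SexChromosomeCall:
    """Nominate the scaffold with the most significant sex-associated
    markers as the putative X chromosome; exact ties are reported as
    ambiguous, never broken silently."""
    counts = scan.per_scaffold_counts
    if counts.empty:
        raise ValueError("no significant markers: no sex-chromosome call")
    top = counts["n_significant"].max()
    tied = counts.loc[counts["n_significant"] == top, "scaffold"].tolist()
    total_sig = len(scan.significant_markers)
    if len(tied) > 1:
        return SexChromosomeCall(
            scaffold=None,
            n_significant=int(top),
            fraction_of_significant=top / total_sig,
            ambiguous=True,
            tied_scaffolds=tied,
        )
    return SexChromosomeCall(
        scaffold=tied[0],
        n_significant=int(top),
        fraction_of_significant=top / total_sig,
        ambiguous=False,
    )


def segregation_qc(gm: GenotypeMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Goodness-of-fit of each marker to the expected test-cross (1:1 A:H)
    or F2 (1:2:1 A:H:B) segregation ratio; markers failing both are flagged
    distorted. A marker-QC aid, not a mapping step."""
    rows = []
    for i, mid in enumerate(gm.marker_ids):
        row = gm.genotypes[i]
        counts = {g: int(np.sum(row == g)) for g in GENOTYPE_CODES}
        n = sum(counts.values())
        if n == 0:
            rows.append({"marker": mid, "model": "none", "p": float("nan"),
                         "distorted": True})
            continue
        if counts["B"] == 0 or counts["A"] == 0:
            # test-cross type: two observed classes expected 1:1
            observed = sorted(counts.values(), reverse=True)[:2]
            stat = sum((o - n / 2) ** 2 / (n / 2) for o in observed)
            p = float(stats.chi2.sf(stat, 1))
            model = "testcross_1:1"
        else:
            expected = np.array([n / 4, n / 2, n / 4])
            observed = np.array([counts["A"], counts["H"], counts["B"]])
            stat = float(((observed - expected) ** 2 / expected).sum())
            p = float(stats.chi2.sf(stat, 2))
            model = "f2_1:2:1"
        rows.append(
            {"marker": mid, "model": model, "p": p, "distorted": p < alpha}
        )
    return pd.DataFrame(rows)


def read_genotype_tsv(path, sex_row: str = "sex") -> GenotypeMatrix:
    """Genotype TSV: markers as rows, individuals as columns, codes
    A/H/B/-; a ``scaffold`` column for physical assignment and one row
    (named by ``sex_row``) giving each individual's sex."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if sex_row not in df.index:
        raise ValueError(f"no {sex_row!r} row in genotype table")
    if "scaffold" not in df.columns:
        raise ValueError("no 'scaffold' column in genotype table")
    sex = df.loc[sex_row].drop("scaffold").tolist()
    body = df.drop(index=sex_row)
    scaffolds = body["scaffold"].tolist()
    geno = body.drop(columns="scaffold")
    return GenotypeMatrix(
        marker_ids=body.index.tolist(),
        individual_ids=geno.columns.tolist(),
        genotypes=geno.to_numpy(dtype="<U1"),
        sex=sex,
        scaffolds=scaffolds,
    )


def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        gm.genotypes, index=gm.marker_ids, columns=gm.individual_ids
    )
    df.insert(0, "scaffold", gm.scaffolds)
    sex_row = pd.DataFrame(
        [["-"] + list(gm.sex)], index=["sex"],
        columns=["scaffold"] + gm.individual_ids,
    )
    pd.concat([sex_row, df]).to_csv(path, sep="\t")
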