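"""Domain types and primitives for per-cytosine methylation data.

The central container is :class:`CytosineMatrix`: per-cytosine methylated and
total read counts across samples, annotated with strand, context (CpG / CHG /
CHH) and trinucleotide. Methylation level beta = meth / total is derived lazily
and is *missing* (NaN), never zero, at uncovered sites.

Coordinates are 1-based in cytosine-report I/O (the native format of
aligner-produced per-cytosine reports) and 0-based half-open in every region
(BED-like) structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "chrom", "pos", "strand", "meth", "unmeth", "context", "trinucleotide",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ReportParseError(ValueError):
    """Raised when a per-cytosine report line cannot be parsed or validated."""


def context_from_trinucleotide(trinucleotide: str) -> str:
    """Cytosine context implied by the trinucleotide starting at the C.

    Second base G -> CpG; else third base G -> CHG; else CHH.
    """
    t = trinucleotide.upper()
    if len(t) != 3 or t[0] != "C":
        raise ValueError(f"not a cytosine trinucleotide: {trinucleotide!r}")
    if t[1] == "G":
        return "CpG"
    if t[2] == "G":
        return "CHG"
    return "CHH"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def annotate_context(sequence: str, pos: int, strand: str) -> tuple[str, str]:
    """Context and trinucleotide of the cytosine at 1-based ``pos``.

    ``sequence`` is the plus-strand reference. On the minus strand the
    trinucleotide reads in minus-strand orientation (reverse complement,
    extending leftwards on the plus strand).

    Raises ``ValueError`` if the addressed base is not a C on the requested
    strand, or if fewer than two downstream bases exist (context
    undeterminable; callers drop such sites).
    """
    i = pos - 1
    if strand == "+":
        if i < 0 or i >= len(sequence) or sequence[i].upper() != "C":
            raise ValueError(f"position {pos} (+) is not a C")
        if i + 3 > len(sequence):
            raise ValueError(f"position {pos} (+): fewer than 2 downstream bases")
        tri = sequence[i : i + 3].upper()
    elif strand == "-":
        if i < 0 or i >= len(sequence) or sequence[i].upper() != "G":
            raise ValueError(f"position {pos} (-) is not a C on the minus strand")
        if i - 2 < 0:
            raise ValueError(f"position {pos} (-): fewer than 2 downstream bases")
        tri = reverse_complement(sequence[i - 2 : i + 1]).upper()
    else:
        raise ValueError(f"invalid strand {strand!r}")
    return context_from_trinucleotide(tri), tri


@dataclass
class CytosineMatrix:
    """Per-cytosine counts across samples.

    Attributes
    ----------
    sites : DataFrame with columns chrom, pos (1-based), strand, context,
        trinucleotide; one row per cytosine, positions strictly increasing
        within (chrom, strand).
    meth, total : int arrays of shape (n_sites, n_samples), 0 <= meth <= total.
    samples : column order of the count arrays.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.meth.ndim == 1:
            self.meth = self.meth[:, None]
        if self.total.ndim == 1:
            self.total = self.total[:, None]
        self.samples = list(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def beta(self) -> np.ndarray:
        """Methylation level meth/total; NaN where total == 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            b = self.meth / self.total.astype(float)
        b[self.total == 0] = np.nan
        return b

    def validate(self) -> None:
        if self.meth.shape != self.total.shape or self.meth.shape[0] != self.n_sites:
            raise ValueError("count array shapes do not match site table")
        if self.meth.shape[1] != self.n_samples:
            raise ValueError("count array width does not match sample list")
        if (self.meth < 0).any() or (self.meth > self.total).any():
            raise ValueError("counts violate 0 <= meth <= total")
        expected = self.sites["trinucleotide"].map(context_from_trinucleotide)
        bad = expected.ne(self.sites["context"])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"context/trinucleotide mismatch at row {i}: "
                f"{self.sites['context'].iat[i]} vs {self.sites['trinucleotide'].iat[i]}"
            )
        for (_, _), grp in self.sites.groupby(["chrom", "strand"], sort=False):
            p = grp["pos"].to_numpy()
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError("positions not strictly increasing within (chrom, strand)")

    def subset(self, mask: np.ndarray) -> "CytosineMatrix":
        mask = np.asarray(mask)
        return CytosineMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            self.meth[mask],
            self.total[mask],
            self.samples,
        )

    def select_context(self, context: str) -> "CytosineMatrix":
        """Subset to a context family: 'CpG', 'CHG', 'CHH', 'CpH', or 'allC'."""
        ctx = self.sites["context"]
        if context == "allC":
            mask = np.ones(self.n_sites, dtype=bool)
        elif context == "CpH":
            mask = ctx.isin(["CHG", "CHH"]).to_numpy()
        else:
            mask = (ctx == context).to_numpy()
        return self.subset(mask)


# ---------------------------------------------------------------------------
# sample metadata

AGE_GROUP_BINS = ((0.0, 1.0, "infant"), (1.0, 10.0, "child"), (10.0, 17.0, "teen"))


def assign_age_group(age: float) -> str:
    """Age group: infant [0,1], child (1,10], teen (10,17], adult (17, inf)."""
    if age < 0:
        raise ValueError("postnatal age must be >= 0")
    for lo, hi, name in AGE_GROUP_BINS:
        if age <= hi:
            return name
    return "adult"


def make_sample_meta(
    sample_id: Sequence[str],
    cell_fraction: Sequence[str],
    age: Sequence[float],
    prenatal: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Build the sample metadata table with the derived age group."""
    meta = pd.DataFrame(
        {
            "sample_id": list(sample_id),
            "cell_fraction": list(cell_fraction),
            "age": np.asarray(age, dtype=float),
        }
    )
    bad = ~meta["cell_fraction"].isin(["neuron", "glia", "homogenate"])
    if bad.any():
        raise ValueError(f"unknown cell fraction: {meta.loc[bad, 'cell_fraction'].iloc[0]!r}")
    meta["prenatal"] = list(prenatal) if prenatal is not None else False
    meta["age_group"] = [assign_age_group(a) for a in meta["age"]]
    return meta


# ---------------------------------------------------------------------------
# cytosine-report I/O

def _read_one_report(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=REPORT_COLUMNS,
            dtype={
                "chrom": str, "strand": str, "context": str, "trinucleotide": str,
            },
        )
    except Exception as exc:  # pragma: no cover - pandas error paths
        raise ReportParseError(f"{path}: {exc}") from exc
    for col in ("pos", "meth", "unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ReportParseError(f"{path}: malformed {col} at line {line}")
        df[col] = vals.astype(np.int64)
    expected = df["trinucleotide"].map(
        lambda t: context_from_trinucleotide(t) if isinstance(t, str) and len(t) == 3 and t.upper().startswith("C") else None
    )
    bad = expected.isna() | expected.ne(df["context"])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ReportParseError(f"{path}: context inconsistent with trinucleotide at line {line}")
    return df


def read_cytosine_report(
    paths: Mapping[str, str | Path],
    samples: Sequence[str] | None = None,
) -> CytosineMatrix:
    """Load per-sample 7-column cytosine reports into one matrix.

    ``paths`` maps sample id -> report path (tab-separated: chrom, 1-based
    position, strand, methylated count, unmethylated count, context,
    trinucleotide). Column order of the result follows ``samples`` when given.
    Sites absent from a sample's report get zero coverage there.
    """
    if samples is None:
        samples = list(paths)
    frames = {s: _read_one_report(paths[s]) for s in samples}
    key = ["chrom", "pos", "strand", "context", "trinucleotide"]
    site_tab = (
        pd.concat([f[key] for f in frames.values()])
        .drop_duplicates()
        .sort_values(["chrom", "pos", "strand"], kind="mergesort")
        .reset_index(drop=True)
    )
    dup = site_tab.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        r = site_tab[dup].iloc[0]
        raise ReportParseError(
            f"conflicting annotation for site {r['chrom']}:{r['pos']}({r['strand']})"
        )
    index = pd.MultiIndex.from_frame(site_tab[["chrom", "pos", "strand"]])
    n = len(site_tab)
    meth = np.zeros((n, len(samples)), dtype=np.int64)
    total = np.zeros_like(meth)
    for j, s in enumerate(samples):
        f = frames[s]
        loc = index.get_indexer(pd.MultiIndex.from_frame(f[["chrom", "pos", "strand"]]))
        meth[loc, j] = f["meth"].to_numpy()
        total[loc, j] = (f["meth"] + f["unmeth"]).to_numpy()
    mat = CytosineMatrix(site_tab, meth, total, list(samples))
    mat.validate()
    return mat


def write_cytosine_report(matrix: CytosineMatrix, sample: str, path: str | Path) -> None:
    """Write one sample back to the 7-column report format (round-trip exact)."""
    j = matrix.samples.index(sample)
    out = matrix.sites[["chrom", "pos", "strand"]].copy()
    out["meth"] = matrix.meth[:, j]
    out["unmeth"] = matrix.total[:, j] - matrix.meth[:, j]
    out["context"] = matrix.sites["context"]
    out["trinucleotide"] = matrix.sites["trinucleotide"]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bed(regions: pd.DataFrame, path: str | Path, score: str | None = None) -> None:
    """Write regions (0-based half-open) as BED6; score column optional."""
    out = pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start"].astype(int),
            "end": regions["end"].astype(int),
            "name": regions.get("kind", pd.Series(["region"] * len(regions))),
            "score": regions[score] if score else 0,
            "strand": ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# filtering and grouping

def filter_by_coverage(
    matrix: CytosineMatrix, min_cov: int, min_positive_samples: int = 0
) -> CytosineMatrix:
    """Keep sites covered >= ``min_cov`` in *every* sample; optionally require
    at least ``min_positive_samples`` samples with beta > 0 (the non-CpG rule).
    """
    mask = (matrix.total >= min_cov).all(axis=1)
    if min_positive_samples > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            positive = (matrix.meth > 0) & (matrix.total > 0)
        mask &= positive.sum(axis=1) >= min_positive_samples
    kept = matrix.subset(mask)
    logger.info(
        "coverage filter (min_cov=%d, min_positive=%d): kept %d / %d sites",
        min_cov, min_positive_samples, kept.n_sites, matrix.n_sites,
    )
    return kept


def cluster_positions(
    positions: np.ndarray,
    max_gap: int,
    chroms: np.ndarray | None = None,
) -> np.ndarray:
    """Group sorted positions into clusters: consecutive sites <= ``max_gap``
    apart share a label. Labels are 0..k-1 in genome order and never span
    chromosomes. Raises on unsorted input (within a chromosome).
    """
    positions = np.asarray(positions)
    n = len(positions)
    if n == 0:
        return np.array([], dtype=np.int64)
    if chroms is None:
        chrom_break = np.zeros(n - 1, dtype=bool)
    else:
        chroms = np.asarray(chroms)
        chrom_break = chroms[1:] != chroms[:-1]
    gaps = np.diff(positions)
    if ((gaps <= 0) & ~chrom_break).any():
        raise ValueError("positions must be strictly increasing within each chromosome")
    new_cluster = chrom_break | (gaps > max_gap)
    labels = np.concatenate([[0], np.cumsum(new_cluster)])
    return labels.astype(np.int64)


def context_accumulation(
    matrix: CytosineMatrix,
    threshold: float = 0.10,
    classes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-sample proportion of sites methylated above ``threshold``, by
    trinucleotide class (e.g. the share of CAC or CAG sites with beta > 10%,
    the statistic used to track non-CpG accumulation across development).

    Only covered sites enter numerator and denominator. Empty classes give NaN.
    Returns a DataFrame indexed by sample with one column per class.
    """
    beta = matrix.beta()
    tri = matrix.sites["trinucleotide"].to_numpy()
    if classes is None:
        classes = sorted(pd.unique(tri))
    out = {}
    for cls in classes:
        rows = tri == cls
        b = beta[rows]
        covered = ~np.isnan(b)
        denom = covered.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = (np.nan_to_num(b) > threshold).sum(axis=0) / denom
        prop[denom == 0] = np.nan
        out[cls] = prop
    return pd.DataFrame(out, index=matrix.samples)
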