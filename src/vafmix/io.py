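"""Reading, validation and filtering of somatic-mutation frequency data.

The analysis operates on the site frequency spectrum of somatic mutations
from a single bulk tumour sample: for every mutation either a variant
allele frequency (VAF = variant reads / total depth) or a cancer cell
fraction (CCF). All frequencies used for fitting must lie strictly inside
(0, 1); CCF values, which range around 1 for clonal mutations, are halved
on input so that a clonal diploid mutation in a pure sample maps to 0.5.

Tables are read with pandas, VCFs with cyvcf2. The canonical in-memory
container is :class:`FrequencyDataset`, a thin wrapper around a pandas
DataFrame with one row per retained mutation and a ``freq`` column holding
the frequency actually used for fitting.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import logger
from .errors import ConfigurationError, ValidationError

#: default column names for delimited input (TSV/CSV)
DEFAULT_COLUMNS: dict[str, str] = {
    "chrom": "chr",
    "pos": "from",
    "ref": "ref",
    "alt": "alt",
    "depth": "DP",
    "alt_reads": "NV",
    "vaf": "VAF",
    "ccf": "CCF",
}

VAF = "VAF"
CCF_HALVED = "CCF_halved"


@dataclass
class MutationRecord:
    """One somatic variant with read counts and its frequency.

    ``vaf`` must equal ``alt_reads / depth`` (within 1e-9) when both counts
    are present; ``ccf`` is the optional raw cancer cell fraction (>= 0,
    <= 2) before halving.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int | None
    alt_reads: int | None
    vaf: float
    ccf: float | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            self.id = f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"
        if self.depth is not None and self.alt_reads is not None:
            if self.alt_reads > self.depth:
                raise ValidationError(
                    f"record {self.id}: alt_reads {self.alt_reads} > depth {self.depth}"
                )
            if self.depth > 0 and abs(self.vaf - self.alt_reads / self.depth) > 1e-9:
                raise ValidationError(
                    f"record {self.id}: vaf {self.vaf} != alt_reads/depth "
                    f"{self.alt_reads / self.depth}"
                )
        if not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"record {self.id}: vaf {self.vaf} outside [0, 1]")


@dataclass
class FrequencyDataset:
    """Ordered collection of mutations with the frequency used for fitting.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per retained mutation. Always contains ``id`` and ``freq``;
        read counts / coordinates / truth annotations are kept when known.
    frequency_kind : str
        ``"VAF"`` or ``"CCF_halved"`` — recorded in downstream outputs for
        provenance.
    min_frequency : float
        Lower analysis cutoff applied to this dataset (0 if unfiltered).
    """

    df: pd.DataFrame
    frequency_kind: str = VAF
    min_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency_kind not in (VAF, CCF_HALVED):
            raise ConfigurationError(
                f"frequency_kind must be {VAF!r} or {CCF_HALVED!r}, "
                f"got {self.frequency_kind!r}"
            )
        if "freq" not in self.df.columns:
            raise ConfigurationError("dataset frame must have a 'freq' column")
        if "id" not in self.df.columns:
            self.df = self.df.copy()
            self.df.insert(0, "id", [f"m{i:06d}" for i in range(len(self.df))])

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def frequencies(self) -> np.ndarray:
        return self.df["freq"].to_numpy(dtype=float)

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()

    def records(self) -> list[MutationRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            out.append(
                MutationRecord(
                    chrom=str(d.get("chrom", "?")),
                    pos=int(d.get("pos", 0)),
                    ref=str(d.get("ref", "N")),
                    alt=str(d.get("alt", "N")),
                    depth=None if pd.isna(d.get("depth", np.nan)) else int(d["depth"]),
                    alt_reads=None
                    if pd.isna(d.get("alt_reads", np.nan))
                    else int(d["alt_reads"]),
                    vaf=float(d.get("vaf", d["freq"])),
                    ccf=None if pd.isna(d.get("ccf", np.nan)) else float(d["ccf"]),
                    id=str(d["id"]),
                )
            )
        return out

    @classmethod
    def from_frequencies(
        cls,
        freqs: Iterable[float],
        frequency_kind: str = VAF,
        ids: Sequence[str] | None = None,
    ) -> "FrequencyDataset":
        freqs = np.asarray(list(freqs), dtype=float)
        if ids is None:
            ids = [f"m{i:06d}" for i in range(freqs.size)]
        df = pd.DataFrame({"id": list(ids), "freq": freqs})
        _check_range(df["freq"].to_numpy(), df["id"].to_numpy())
        return cls(df, frequency_kind=frequency_kind)


def _check_range(freq: np.ndarray, ids: np.ndarray) -> None:
    bad = ~((freq >= 0.0) & (freq <= 1.0))
    if np.any(bad):
        offenders = ", ".join(map(str, ids[bad][:10]))
        more = "" if bad.sum() <= 10 else f" (+{int(bad.sum()) - 10} more)"
        raise ValidationError(
            f"{int(bad.sum())} frequencies outside [0, 1]: {offenders}{more}"
        )


def adjust_ccf(raw_ccf) -> np.ndarray:
    """Halve raw CCF values so that clonal (CCF=1) maps to frequency 0.5.

    Values in (1, 2] are legal before halving (multi-copy states); a halved
    value above 1 (raw CCF > 2) is not representable and is rejected.
    """
    raw = np.asarray(raw_ccf, dtype=float)
    if np.any(raw < 0):
        raise ValidationError("CCF values must be >= 0")
    halved = raw / 2.0
    if np.any(halved > 1.0):
        bad = np.flatnonzero(halved > 1.0)
        raise ValidationError(
            f"{bad.size} CCF values > 2 are not representable after halving "
            f"(first offending index {bad[0]}, value {raw[bad[0]]})"
        )
    return halved


def read_table(
    path,
    column_map: Mapping[str, str] | None = None,
    frequency_kind: str = VAF,
    sep: str | None = None,
) -> FrequencyDataset:
    """Read a delimited mutation table into a :class:`FrequencyDataset`.

    The frequency column is, in order of preference: the mapped ``vaf``
    column (or ``ccf`` when ``frequency_kind`` refers to CCF input), else
    the ratio of mapped ``alt_reads`` / ``depth`` columns. Rows with
    missing frequency are dropped with a logged count; any frequency
    outside [0, 1] (after CCF halving) raises a validation error.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    table = pd.read_csv(path, sep=sep)

    use_ccf = frequency_kind in (CCF_HALVED, "CCF", "ccf")
    df = pd.DataFrame()
    for fld in ("chrom", "pos", "ref", "alt"):
        if cols[fld] in table.columns:
            df[fld] = table[cols[fld]]
    have_counts = cols["depth"] in table.columns and cols["alt_reads"] in table.columns
    if have_counts:
        df["depth"] = pd.to_numeric(table[cols["depth"]], errors="coerce")
        df["alt_reads"] = pd.to_numeric(table[cols["alt_reads"]], errors="coerce")

    if use_ccf:
        if cols["ccf"] not in table.columns:
            raise ConfigurationError(
                f"frequency_kind=CCF requires column {cols['ccf']!r}"
            )
        raw = pd.to_numeric(table[cols["ccf"]], errors="coerce")
        df["ccf"] = raw
        freq = pd.Series(np.nan, index=table.index)
        ok = raw.notna()
        freq[ok] = adjust_ccf(raw[ok].to_numpy())
        kind = CCF_HALVED
    else:
        if cols["vaf"] in table.columns:
            freq = pd.to_numeric(table[cols["vaf"]], errors="coerce")
        elif have_counts:
            freq = df["alt_reads"] / df["depth"]
        else:
            raise ConfigurationError(
                f"missing required column: either {cols['vaf']!r} or both "
                f"{cols['depth']!r} and {cols['alt_reads']!r}"
            )
        kind = VAF
    df["vaf"] = freq if kind == VAF else np.nan
    df["freq"] = freq

    if "chrom" in df.columns and "pos" in df.columns:
        ids = (
            df["chrom"].astype(str)
            + ":"
            + df["pos"].astype(str)
            + ":"
            + (df["ref"].astype(str) if "ref" in df else "N")
            + ">"
            + (df["alt"].astype(str) if "alt" in df else "N")
        )
    else:
        ids = pd.Series([f"m{i:06d}" for i in range(len(df))])
    df.insert(0, "id", ids)

    n_missing = int(df["freq"].isna().sum())
    if n_missing:
        logger.info("read_table: dropped %d rows with missing frequency", n_missing)
        df = df[df["freq"].notna()].reset_index(drop=True)
    _check_range(df["freq"].to_numpy(), df["id"].to_numpy())

    if have_counts:
        counts_ok = df["depth"].notna() & df["alt_reads"].notna() & (df["depth"] > 0)
        if kind == VAF and counts_ok.any():
            recomputed = df.loc[counts_ok, "alt_reads"] / df.loc[counts_ok, "depth"]
            mism = (recomputed - df.loc[counts_ok, "freq"]).abs() > 1e-3
            if mism.any():
                logger.warning(
                    "read_table: %d rows where VAF column disagrees with "
                    "alt_reads/depth by > 1e-3",
                    int(mism.sum()),
                )
    return FrequencyDataset(df.reset_index(drop=True), frequency_kind=kind)


def write_table(dataset: FrequencyDataset, path, clusters=None) -> Path:
    """Write a dataset as TSV (default column names), optionally with a
    ``cluster`` column of hard assignments."""
    path = Path(path)
    df = dataset.df.copy()
    out = pd.DataFrame()
    mapping = [
        ("chrom", DEFAULT_COLUMNS["chrom"]),
        ("pos", DEFAULT_COLUMNS["pos"]),
        ("ref", DEFAULT_COLUMNS["ref"]),
        ("alt", DEFAULT_COLUMNS["alt"]),
        ("depth", DEFAULT_COLUMNS["depth"]),
        ("alt_reads", DEFAULT_COLUMNS["alt_reads"]),
    ]
    out["id"] = df["id"]
    for src, dst in mapping:
        if src in df.columns:
            out[dst] = df[src]
    if dataset.frequency_kind == CCF_HALVED and "ccf" in df.columns:
        out[DEFAULT_COLUMNS["ccf"]] = df["ccf"]
    out[DEFAULT_COLUMNS["vaf"]] = df["freq"] if dataset.frequency_kind == VAF else df["vaf"]
    out["freq"] = df["freq"]
    for extra in ("clone_label", "true_vaf", "carriers"):
        if extra in df.columns:
            out[extra] = df[extra]
    if clusters is not None:
        out["cluster"] = np.asarray(clusters)
    out.to_csv(path, sep="\t", index=False)
    return path


def read_vcf(path, sample: str | None = None) -> FrequencyDataset:
    """Read somatic mutations from a VCF, one record per biallelic variant.

    The VAF is computed from per-sample allelic depths (FORMAT ``AD``,
    ref/alt read counts), with total depth from ``DP`` when present and
    from the AD sum otherwise. Multiallelic rows are skipped with a logged
    count; zero-depth records are dropped with a logged count.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ConfigurationError("VCF has no sample columns")
    if sample is None:
        if len(samples) > 1:
            raise ConfigurationError(
                f"VCF has multiple samples; choose one of: {', '.join(samples)}"
            )
        sidx = 0
    else:
        if sample not in samples:
            raise ConfigurationError(
                f"sample {sample!r} not in VCF; available: {', '.join(samples)}"
            )
        sidx = samples.index(sample)

    rows = []
    n_multi = 0
    n_zero = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise ConfigurationError(
                "VCF is missing the per-sample FORMAT field 'AD' "
                "(allelic depths) needed to compute VAF"
            )
        ref_reads = int(ad[sidx][0])
        alt_reads = int(ad[sidx][1])
        dp = v.format("DP")
        depth = int(dp[sidx][0]) if dp is not None else max(ref_reads, 0) + max(alt_reads, 0)
        if depth <= 0 or alt_reads < 0:
            n_zero += 1
            continue
        rows.append(
            dict(
                chrom=v.CHROM,
                pos=int(v.POS),
                ref=v.REF,
                alt=v.ALT[0],
                depth=depth,
                alt_reads=alt_reads,
                vaf=alt_reads / depth,
            )
        )
    if n_multi:
        logger.info("read_vcf: skipped %d multiallelic rows", n_multi)
    if n_zero:
        logger.warning("read_vcf: dropped %d zero-depth records", n_zero)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "depth", "alt_reads", "vaf"])
    df["freq"] = df["vaf"]
    df.insert(
        0,
        "id",
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(str)
        + ":"
        + df["ref"].astype(str)
        + ">"
        + df["alt"].astype(str),
    )
    _check_range(df["freq"].to_numpy(), df["id"].to_numpy())
    ds = FrequencyDataset(df, frequency_kind=VAF)
    ds.n_zero_depth_dropped = n_zero  # type: ignore[attr-defined]
    ds.n_multiallelic_skipped = n_multi  # type: ignore[attr-defined]
    return ds


def filter_dataset(dataset: FrequencyDataset, min_vaf: float) -> FrequencyDataset:
    """Retain mutations with frequency strictly above ``min_vaf`` and < 1.

    "Above" is implemented as a strict inequality, and frequencies of
    exactly 0 or 1 are always excluded (the Beta and Pareto densities live
    on the open interval). Raises if nothing survives.
    """
    if not (0.0 <= min_vaf < 1.0):
        raise ConfigurationError(f"min_vaf must be in [0, 1), got {min_vaf}")
    freq = dataset.frequencies
    keep = (freq > min_vaf) & (freq < 1.0)
    n_drop = int((~keep).sum())
    if not keep.any():
        raise ValidationError(
            f"no mutations retained at cutoff {min_vaf}; lower the cutoff"
        )
    logger.info(
        "filter_dataset: retained %d, dropped %d at cutoff %g",
        int(keep.sum()),
        n_drop,
        min_vaf,
    )
    return replace(
        dataset,
        df=dataset.df.loc[keep].reset_index(drop=True),
        min_frequency=min_vaf,
    )
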