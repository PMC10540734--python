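"""Shared data model and delimited-text / FASTA / JSON input-output.

The pipeline starts from quantified feature tables (one abundance column per
sample), not from raw spectra.  Sample columns follow the dialect
``<condition>_ZT<zt>_<replicate>``, e.g. ``LD_ZT8_C``: condition is the
lighting regime (LD = entrained light--dark cycle, DA = dark adaptation),
ZT is Zeitgeber time in hours after lights-on, and the replicate is a
single-letter label (A--E for a five-replicate design).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("LD", "DA")

_SAMPLE_RE = re.compile(r"^(?P<cond>[A-Za-z]+)_ZT(?P<zt>\d+(?:\.\d+)?)_(?P<rep>[A-Za-z0-9]+)$")

#: phosphorylatable residues
PHOSPHO_RESIDUES = frozenset("STY")


class TableFormatError(ValueError):
    """Raised when a quantification table violates the format contract."""


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one measured sample: (condition, Zeitgeber time, replicate)."""

    condition: str
    zt: float
    replicate: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if self.zt < 0:
            raise ValueError(f"Zeitgeber time must be non-negative, got {self.zt}")

    @property
    def label(self) -> str:
        zt = int(self.zt) if float(self.zt).is_integer() else self.zt
        return f"{self.condition}_ZT{zt}_{self.replicate}"

    @classmethod
    def parse(cls, name: str) -> "SampleKey":
        m = _SAMPLE_RE.match(name)
        if m is None:
            raise ValueError(
                f"sample column {name!r} does not match '<condition>_ZT<zt>_<replicate>'"
            )
        return cls(m.group("cond"), float(m.group("zt")), m.group("rep"))


def is_sample_column(name: str) -> bool:
    return _SAMPLE_RE.match(name) is not None


class QuantTable:
    """A features x samples abundance matrix with typed sample metadata.

    Parameters
    ----------
    data
        DataFrame indexed by unique feature id; every column name must parse
        as a :class:`SampleKey`.  Missing abundances are stored as NaN (never
        imputed as zero); downstream means use available replicates only.
    locus
        Optional mapping feature id -> protein locus (for peptide- or
        motif-level tables).
    normalized, transformed
        Provenance flags set by the preprocessing steps.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        locus: pd.Series | Mapping[str, str] | None = None,
        normalized: bool = False,
        transformed: bool = False,
    ) -> None:
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate feature ids: {dupes[:5]}")
        keys = [SampleKey.parse(c) for c in data.columns]
        if len(set(keys)) != len(keys):
            raise TableFormatError("duplicate sample columns")
        if not transformed:
            vals = data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) < 0:
                r, c = np.argwhere(np.asarray(data < 0))[0]
                raise TableFormatError(
                    f"negative abundance at feature {data.index[r]!r}, sample {data.columns[c]!r}"
                )
        self.data = data.astype(float)
        self.locus = None if locus is None else pd.Series(locus).reindex(data.index)
        self.normalized = normalized
        self.transformed = transformed

    # -- basic introspection -------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_keys(self) -> list[SampleKey]:
        return [SampleKey.parse(c) for c in self.data.columns]

    @property
    def n_features(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        flags = []
        if self.normalized:
            flags.append("normalized")
        if self.transformed:
            flags.append("transformed")
        tag = f" [{', '.join(flags)}]" if flags else ""
        return f"<QuantTable {self.n_features} features x {self.data.shape[1]} samples{tag}>"

    def timepoint_columns(self) -> dict[tuple[str, float], list[str]]:
        """Sample columns grouped by (condition, zt), replicates in label order."""
        groups: dict[tuple[str, float], list[str]] = {}
        for col in self.data.columns:
            k = SampleKey.parse(col)
            groups.setdefault((k.condition, k.zt), []).append(col)
        return groups

    def timepoint_means(self, condition: str | None = None) -> pd.DataFrame:
        """Within-timepoint means over available replicates (features x zt)."""
        cols = self.timepoint_columns()
        out = {}
        for (cond, zt), cc in sorted(cols.items()):
            if condition is not None and cond != condition:
                continue
            out[zt] = self.data[cc].mean(axis=1)
        return pd.DataFrame(out)

    def copy(self, **updates) -> "QuantTable":
        kw = dict(
            data=self.data.copy(),
            locus=None if self.locus is None else self.locus.copy(),
            normalized=self.normalized,
            transformed=self.transformed,
        )
        kw.update(updates)
        return QuantTable(**kw)

    def drop_samples(self, keys: Iterable[SampleKey]) -> "QuantTable":
        labels = {k.label for k in keys}
        keep = [c for c in self.data.columns if c not in labels]
        return self.copy(data=self.data[keep])


@dataclass
class PhosphoVariant:
    """One technical phosphopeptide species before merging.

    The same phosphorylation event is typically observed as several species
    differing in charge state (2+ to 4+), missed tryptic cleavages, and
    co-modifications such as methionine oxidation or N-terminal acetylation.
    ``phospho_positions`` are 1-based residue indices on the protein.
    """

    feature_id: str
    locus: str
    sequence: str
    charge: int
    missed_cleavages: int
    modifications: frozenset[str]
    phospho_positions: tuple[int, ...]
    abundance: pd.Series  # indexed by sample label
    phospho_residues: tuple[str, ...] = ()
    localization: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.phospho_positions = tuple(sorted(int(p) for p in self.phospho_positions))
        self.modifications = frozenset(self.modifications)
        if not 2 <= self.charge <= 4:
            raise ValueError(f"charge {self.charge} outside 2-4 for {self.feature_id}")
        if self.missed_cleavages < 0:
            raise ValueError("missed cleavages must be >= 0")
        for r in self.phospho_residues:
            if r not in PHOSPHO_RESIDUES:
                raise ValueError(f"phosphorylated residue {r!r} not in S/T/Y ({self.feature_id})")

    @property
    def site_key(self) -> tuple[str, tuple[int, ...]]:
        return (self.locus, self.phospho_positions)

    @property
    def n_mods(self) -> int:
        """Co-modification count used as part of the cross-referencing key."""
        return len(self.modifications)


@dataclass
class PhosphoMotif:
    """The merged, uniquely keyed unit of phospho-quantification.

    All peptide species sharing phosphorylation of the same residue set on a
    protein, summed over charge states, missed cleavages and co-modifications.
    A doubly-phosphorylated site set is a distinct motif from its singly-
    phosphorylated subsets.
    """

    locus: str
    positions: tuple[int, ...]
    abundance: pd.Series
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        self.positions = tuple(sorted(int(p) for p in self.positions))

    @property
    def motif_id(self) -> str:
        return f"{self.locus}@{'+'.join(str(p) for p in self.positions)}"


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_VARIANT_META = [
    "feature_id",
    "locus",
    "sequence",
    "charge",
    "missed_cleavages",
    "modifications",
    "phospho_positions",
]


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_abundance_block(df: pd.DataFrame, sample_cols: Sequence[str], path: Path) -> pd.DataFrame:
    block = df[list(sample_cols)].apply(pd.to_numeric, errors="coerce")
    raw_na = df[list(sample_cols)].isna()
    bad = block.isna() & ~raw_na
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise TableFormatError(
            f"{path}: malformed abundance {df[sample_cols].iat[r, c]!r} "
            f"at row {r + 2}, column {sample_cols[c]!r}"
        )
    return block


def read_quant_table(
    path: str | Path,
    schema: str = "protein",
    expect_samples: Sequence[str] | None = None,
    column_map: Mapping[str, str] | None = None,
):
    """Read a delimited quantification table.

    ``schema`` is one of ``protein``, ``rna``, ``motif`` (returning a
    :class:`QuantTable`) or ``variant`` (returning a list of
    :class:`PhosphoVariant`).  TSV/CSV is auto-detected from the extension.
    ``column_map`` renames foreign headers to the
    ``<condition>_ZT<zt>_<replicate>`` dialect before parsing.
    """
    path = Path(path)
    if schema not in {"protein", "rna", "motif", "variant"}:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, sep=_delimiter(path), dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    sample_cols = [c for c in df.columns if is_sample_column(c)]
    if not sample_cols:
        raise TableFormatError(f"{path}: no sample columns matching '<cond>_ZT<zt>_<rep>'")
    if expect_samples is not None:
        missing = sorted(set(expect_samples) - set(sample_cols))
        if missing:
            raise TableFormatError(f"{path}: missing sample columns: {missing}")
    block = _check_abundance_block(df, sample_cols, path)

    if schema == "variant":
        missing_meta = [c for c in _VARIANT_META if c not in df.columns]
        if missing_meta:
            raise TableFormatError(f"{path}: variant schema missing columns {missing_meta}")
        if df["feature_id"].duplicated().any():
            dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise TableFormatError(f"{path}: duplicate feature id {dup!r}")
        variants = []
        for i, row in df.iterrows():
            mods = row["modifications"]
            mods = frozenset(m for m in str(mods).split(";") if m and m != "nan") if pd.notna(mods) else frozenset()
            pos = tuple(int(p) for p in str(row["phospho_positions"]).split(";") if p)
            variants.append(
                PhosphoVariant(
                    feature_id=row["feature_id"],
                    locus=row["locus"],
                    sequence=row["sequence"],
                    charge=int(row["charge"]),
                    missed_cleavages=int(row["missed_cleavages"]),
                    modifications=mods,
                    phospho_positions=pos,
                    abundance=block.loc[i, sample_cols].rename(row["feature_id"]),
                )
            )
        return variants

    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df.loc[df[id_col].duplicated(), id_col].iloc[0]
        raise TableFormatError(f"{path}: duplicate feature id {dup!r}")
    data = block.copy()
    data.index = pd.Index(df[id_col], name=id_col)
    locus = None
    if "locus" in df.columns and "locus" != id_col:
        locus = pd.Series(df["locus"].to_numpy(), index=data.index)
    elif schema == "motif":
        locus = pd.Series([fid.split("@")[0] for fid in data.index], index=data.index)
    return QuantTable(data, locus=locus)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _format_float(x) -> str:
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return ""
        return f"{x:.10g}"
    return str(x)


def write_quant_table(table: QuantTable, path: str | Path) -> Path:
    """Write a QuantTable back to delimited text (inverse of read_quant_table)."""
    path = Path(path)
    df = table.data.copy()
    if table.locus is not None:
        df.insert(0, "locus", table.locus)
    out = df.reset_index()
    out.columns = ["feature_id"] + list(df.columns)
    out.to_csv(path, sep=_delimiter(path), index=False, float_format="%.10g")
    return path


def write_variants(variants: Sequence[PhosphoVariant], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for v in variants:
        row = {
            "feature_id": v.feature_id,
            "locus": v.locus,
            "sequence": v.sequence,
            "charge": v.charge,
            "missed_cleavages": v.missed_cleavages,
            "modifications": ";".join(sorted(v.modifications)),
            "phospho_positions": ";".join(str(p) for p in v.phospho_positions),
        }
        row.update(v.abundance.to_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_delimiter(path), index=False, float_format="%.10g")
    return path


def write_results(results, path: str | Path, format: str = "tsv") -> Path:
    """Serialize a result set (DataFrame or list of records) deterministically.

    Columns keep their given order; floats are written with 10 significant
    digits so a write/read round trip is stable to ~1e-10 relative.
    """
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame(list(results))
    if df.empty:
        raise ValueError("refusing to write an empty result set")
    if format == "tsv":
        df.to_csv(path, sep="\t", index=not isinstance(df.index, pd.RangeIndex), float_format="%.10g")
    elif format == "json":
        records = []
        idx_name = df.index.name
        for idx, row in df.iterrows():
            rec = {} if isinstance(df.index, pd.RangeIndex) else {idx_name or "index": idx}
            for k, v in row.items():
                if isinstance(v, (float, np.floating)):
                    rec[k] = None if np.isnan(v) else float(f"{v:.10g}")
                elif isinstance(v, (np.integer,)):
                    rec[k] = int(v)
                elif isinstance(v, (np.bool_,)):
                    rec[k] = bool(v)
                else:
                    rec[k] = v
            records.append(rec)
        path.write_text(json.dumps(records, indent=1) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record id (first token of the header)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> Path:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    seqio_write(records, str(path), "fasta")
    return Path(path)
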