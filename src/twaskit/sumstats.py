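"""GWAS summary-statistic loading, quality control, and allele harmonization.

Summary statistics are held as a :class:`SumStats`: a validated, position-
sorted table of per-SNP Wald Z-scores plus a provenance log of every QC
action applied.  QC mirrors standard summary-statistic munging: a MAF floor,
removal of strand-ambiguous variants (A/T and C/G), and an rsID pattern
check.  Harmonization intersects the statistics with an LD reference's
allele frame, flipping Z signs for swapped alleles and resolving strand
flips by complementing (safe only because ambiguous pairs were removed
upstream).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from twaskit.exceptions import ConfigError, EmptyResultError, ValidationError

#: canonical internal column names -> default file column names
DEFAULT_COLUMNS = {
    "snp": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "z": "Z",
    "maf": "MAF",
    "n": "N",
    "beta": "BETA",
    "se": "SE",
}

REQUIRED = ("snp", "chrom", "pos", "a1", "a2", "maf", "n")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_RSID_RE = re.compile(r"^rs[0-9]+$")


@dataclass
class SumStats:
    """Ordered per-SNP GWAS association records with a QC provenance log.

    ``table`` columns: snp, chrom, pos, a1 (effect allele), a2, z, maf, n.
    Rows are unique on ``snp`` and sorted by (chrom, pos) unless an explicit
    reference order was imposed by :func:`harmonize_alleles`.
    """

    table: pd.DataFrame
    log: list[tuple[str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    def record(self, rule: str, n_removed: int) -> None:
        self.log.append((rule, int(n_removed)))

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log, columns=["rule", "n_removed"])

    def pvalues(self) -> np.ndarray:
        """Two-tailed normal P-values for the Z column."""
        from scipy.stats import norm

        return 2.0 * norm.sf(np.abs(self.table["z"].to_numpy()))


def _validate(table: pd.DataFrame) -> None:
    dup = table["snp"][table["snp"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicated SNP id(s): {', '.join(dup.unique()[:5])}")
    same = table["a1"] == table["a2"]
    if same.any():
        bad = table.loc[same, "snp"].iloc[0]
        raise ValidationError(f"identical effect/other allele for SNP {bad}")


def load_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
) -> SumStats:
    """Read whitespace/tab-delimited summary statistics.

    ``column_map`` maps internal names (keys of :data:`DEFAULT_COLUMNS`) to
    the file's header names.  A ``z`` column is required unless both ``beta``
    and ``se`` are resolvable, in which case z := beta / se.  An allele
    *frequency* column may be supplied as ``maf``; it is folded to
    min(f, 1 - f).  Rows that fail numeric parsing are dropped and counted in
    the provenance log.
    """
    cols = dict(DEFAULT_COLUMNS)
    cols.update(column_map or {})
    raw = pd.read_csv(path, sep=r"\s+", dtype=str)

    for key in REQUIRED:
        if cols[key] not in raw.columns:
            raise ConfigError(
                f"required column '{cols[key]}' (for field '{key}') not found in {path}"
            )
    have_z = cols["z"] in raw.columns
    have_beta = cols["beta"] in raw.columns and cols["se"] in raw.columns
    if not (have_z or have_beta):
        raise ConfigError(
            f"neither a Z column ('{cols['z']}') nor BETA+SE "
            f"('{cols['beta']}'/'{cols['se']}') found in {path}"
        )

    table = pd.DataFrame(
        {
            "snp": raw[cols["snp"]].astype(str),
            "chrom": raw[cols["chrom"]].astype(str),
            "a1": raw[cols["a1"]].str.upper(),
            "a2": raw[cols["a2"]].str.upper(),
        }
    )
    numeric = {"pos": cols["pos"], "maf": cols["maf"], "n": cols["n"]}
    for name, col in numeric.items():
        table[name] = pd.to_numeric(raw[col], errors="coerce")
    if have_z:
        table["z"] = pd.to_numeric(raw[cols["z"]], errors="coerce")
    else:
        beta = pd.to_numeric(raw[cols["beta"]], errors="coerce")
        se = pd.to_numeric(raw[cols["se"]], errors="coerce")
        table["z"] = beta / se

    ok = (
        table[["pos", "maf", "n", "z"]].notna().all(axis=1)
        & np.isfinite(table["z"])
        & table["a1"].isin(_COMPLEMENT)
        & table["a2"].isin(_COMPLEMENT)
    )
    n_malformed = int((~ok).sum())
    table = table.loc[ok].copy()
    table["pos"] = table["pos"].astype(int)
    table["n"] = table["n"].astype(float)
    # fold a frequency column to MAF
    table["maf"] = np.minimum(table["maf"], 1.0 - table["maf"])
    _validate(table)
    table = table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    ss = SumStats(table[["snp", "chrom", "pos", "a1", "a2", "z", "maf", "n"]])
    ss.record("malformed_rows", n_malformed)
    return ss


def save_sumstats(ss: SumStats, path: str | Path, log_path: str | Path | None = None) -> None:
    out = ss.table.rename(
        columns={k: DEFAULT_COLUMNS[k] for k in ss.table.columns if k in DEFAULT_COLUMNS}
    )
    out.to_csv(path, sep="\t", index=False)
    if log_path is not None:
        ss.log_frame().to_csv(log_path, sep="\t", index=False)


def qc_sumstats(
    ss: SumStats,
    maf_min: float = 0.01,
    rsid_required: bool = True,
) -> SumStats:
    """Apply the QC filters: MAF floor, strand-ambiguous removal, rsID check.

    Idempotent; every rule's removal count is appended to the provenance log.
    Raises :class:`EmptyResultError` with the per-rule breakdown if no record
    survives.
    """
    t = ss.table
    low_maf = t["maf"] < maf_min
    ambiguous = pd.Series(
        list(zip(t["a1"], t["a2"])), index=t.index
    ).isin(_AMBIGUOUS)
    bad_id = (
        ~t["snp"].str.match(_RSID_RE)
        if rsid_required
        else pd.Series(False, index=t.index)
    )
    keep = ~(low_maf | ambiguous | bad_id)
    breakdown = {
        "maf_below_min": int(low_maf.sum()),
        "strand_ambiguous": int(ambiguous.sum()),
        "invalid_rsid": int(bad_id.sum()),
    }
    if not keep.any():
        raise EmptyResultError("QC removed every record", breakdown)
    out = SumStats(t.loc[keep].reset_index(drop=True), list(ss.log))
    # counts are attributed disjointly so removals sum to |input| - |output|
    removed = t.loc[~keep]
    out.record("maf_below_min", int((removed["maf"] < maf_min).sum()))
    amb_rem = pd.Series(
        list(zip(removed["a1"], removed["a2"])), index=removed.index
    ).isin(_AMBIGUOUS) & ~(removed["maf"] < maf_min)
    out.record("strand_ambiguous", int(amb_rem.sum()))
    out.record("invalid_rsid", int(len(removed) - (removed["maf"] < maf_min).sum() - amb_rem.sum()))
    return out


def harmonize_alleles(ss: SumStats, bim: pd.DataFrame | list[tuple]) -> SumStats:
    """Intersect with a reference allele frame, aligning effect alleles.

    ``bim`` is a DataFrame with columns (snp, a1, a2) or a sequence of such
    tuples; the output follows the reference order.  For each shared SNP:

    - alleles match the reference  -> record kept as-is
    - alleles swapped              -> z sign flipped, alleles relabelled
    - strand-flipped (complement)  -> complemented then matched as above
    - anything else                -> dropped and logged

    Raises :class:`EmptyResultError` on empty intersection.
    """
    if not isinstance(bim, pd.DataFrame):
        bim = pd.DataFrame(bim, columns=["snp", "a1", "a2"])
    bim = bim[["snp", "a1", "a2"]].copy()
    bim["a1"] = bim["a1"].str.upper()
    bim["a2"] = bim["a2"].str.upper()

    merged = bim.merge(
        ss.table, on="snp", how="inner", suffixes=("_ref", ""), sort=False
    )
    if merged.empty:
        raise EmptyResultError("no SNPs shared with the reference frame")

    a1c = merged["a1"].map(_COMPLEMENT)
    a2c = merged["a2"].map(_COMPLEMENT)
    match = (merged["a1"] == merged["a1_ref"]) & (merged["a2"] == merged["a2_ref"])
    swap = (merged["a1"] == merged["a2_ref"]) & (merged["a2"] == merged["a1_ref"])
    flip_match = (a1c == merged["a1_ref"]) & (a2c == merged["a2_ref"]) & ~match & ~swap
    flip_swap = (a1c == merged["a2_ref"]) & (a2c == merged["a1_ref"]) & ~match & ~swap
    keep = match | swap | flip_match | flip_swap
    n_mismatch = int((~keep).sum())

    out = merged.loc[keep].copy()
    sign = np.where((swap | flip_swap)[keep], -1.0, 1.0)
    out["z"] = out["z"].to_numpy() * sign
    out["a1"] = out["a1_ref"]
    out["a2"] = out["a2_ref"]
    out = out[["snp", "chrom", "pos", "a1", "a2", "z", "maf", "n"]].reset_index(drop=True)
    res = SumStats(out, list(ss.log))
    res.record("allele_mismatch", n_mismatch)
    res.record("not_in_reference", len(ss) - len(merged))
    return res
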