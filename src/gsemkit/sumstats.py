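"""Reading, validation, harmonization and merging of GWAS summary statistics.

Sumstats follow the munged layout (SNP, A1, A2, Z, N, optionally MAF and
INFO), whitespace- or tab-delimited with a header; gzip is handled
transparently by pandas.  Harmonization aligns every table's effect
allele to a declared reference: swapped alleles negate Z, strand flips
are complemented onto the reference strand, strand-ambiguous variants
(A/T, C/G) are always dropped (no allele-frequency reference is
assumed), and irreconcilable records are removed.  All removals are
counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .ldblocks import LdScorePanel
from .panel import HarmonizedPanel, context_key, default_blocks

__all__ = [
    "SumstatsTable",
    "SchemaError",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "qc_filter",
    "merge_panel",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["SNP", "A1", "A2", "Z", "N"]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class SchemaError(ValueError):
    """Input does not match the expected sumstats schema."""


@dataclass
class SumstatsTable:
    """Per-variant association records for one trait."""

    data: pd.DataFrame
    trait: str = ""
    population: str = ""
    log: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        dup = self.data["SNP"].duplicated()
        if dup.any():
            first = self.data.loc[dup, "SNP"].iloc[0]
            raise SchemaError(f"duplicate variant id (first offender: {first!r})")
        if (self.data["N"] <= 0).any():
            raise SchemaError("N must be positive for every record")

    def __len__(self):
        return len(self.data)


def read_sumstats(path, column_map: dict = None, trait: str = "",
                  population: str = "") -> SumstatsTable:
    """Read a sumstats file; rows with missing Z or N are dropped (logged)."""
    df = pd.read_csv(path, sep=r"\s+")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    df["Z"] = pd.to_numeric(df["Z"], errors="coerce")
    df["N"] = pd.to_numeric(df["N"], errors="coerce")
    before = len(df)
    df = df.dropna(subset=["Z", "N"]).reset_index(drop=True)
    df = df[np.isfinite(df["Z"])].reset_index(drop=True)
    dropped = before - len(df)
    if dropped:
        logger.info("%s: dropped %d record(s) with missing/non-finite Z or N",
                    path, dropped)
    for col in ("A1", "A2"):
        df[col] = df[col].astype(str).str.upper()
    return SumstatsTable(data=df, trait=trait or str(path), population=population,
                         log={"n_read": before, "n_dropped_missing": dropped})


def write_sumstats(table: SumstatsTable, path) -> None:
    cols = [c for c in ["SNP", "A1", "A2", "Z", "N", "MAF", "INFO"]
            if c in table.data.columns]
    table.data[cols].to_csv(path, sep="\t", index=False)


def _classify(a1, a2, ref1, ref2):
    """Vectorized allele reconciliation against the reference.

    Codes: 0 keep, 1 swap (negate Z), 2 strand flip, 3 flip+swap,
    4 ambiguous, 5 irreconcilable.
    """
    comp1 = np.array([_COMPLEMENT.get(a, "?") for a in a1])
    comp2 = np.array([_COMPLEMENT.get(a, "?") for a in a2])
    amb = np.array([frozenset({x, y}) in _AMBIGUOUS for x, y in zip(a1, a2)],
                   dtype=bool)
    code = np.full(len(a1), 5, dtype=int)
    code[(a1 == ref1) & (a2 == ref2)] = 0
    code[(a1 == ref2) & (a2 == ref1)] = 1
    code[(comp1 == ref1) & (comp2 == ref2) & (code == 5)] = 2
    code[(comp1 == ref2) & (comp2 == ref1) & (code == 5)] = 3
    code[amb] = 4
    return code


def harmonize(tables: list, reference: pd.DataFrame = None) -> list:
    """Align effect alleles across tables to a shared reference.

    ``reference`` needs columns SNP, A1, A2; by default the first
    table's (non-ambiguous) assignments are used.  Returns new tables;
    per-category removal counts land in each table's ``log``.
    """
    if not tables:
        raise ValueError("need at least one table")
    if reference is None:
        reference = tables[0].data[["SNP", "A1", "A2"]]
    ref = reference.set_index("SNP")
    out = []
    for tab in tables:
        df = tab.data
        present = df["SNP"].isin(ref.index).to_numpy()
        df_in = df[present]
        r = ref.loc[df_in["SNP"]]
        code = _classify(df_in["A1"].to_numpy(), df_in["A2"].to_numpy(),
                         r["A1"].to_numpy(), r["A2"].to_numpy())
        new = df_in.copy()
        swapmask = (code == 1) | (code == 3)
        new.loc[swapmask, "Z"] = -new.loc[swapmask, "Z"]
        new["A1"] = r["A1"].to_numpy()
        new["A2"] = r["A2"].to_numpy()
        keep = code <= 3
        removed = {
            "not_in_reference": int((~present).sum()),
            "strand_ambiguous": int((code == 4).sum()),
            "irreconcilable": int((code == 5).sum()),
            "swapped": int((code == 1).sum()),
            "strand_flipped": int(((code == 2) | (code == 3)).sum()),
        }
        for k, v in removed.items():
            if v and k in ("not_in_reference", "strand_ambiguous", "irreconcilable"):
                logger.info("harmonize[%s]: removed %d %s record(s)",
                            tab.trait, v, k)
        out.append(SumstatsTable(
            data=new[keep].reset_index(drop=True),
            trait=tab.trait, population=tab.population,
            log={**tab.log, "harmonize": removed},
        ))
    return out


def qc_filter(table: SumstatsTable, min_maf: float = 0.01,
              min_info: float = 0.9, max_chisq: float = None) -> SumstatsTable:
    """Conventional LDSC-style QC.

    MAF and INFO filters apply only when the columns exist (a warning
    is logged otherwise); ``max_chisq`` defaults to max(80, 0.001 * N).
    """
    df = table.data
    keep = np.ones(len(df), dtype=bool)
    counts = {}
    if max_chisq is None:
        max_chisq = max(80.0, 0.001 * float(df["N"].median())) if len(df) else 80.0
    chisq = df["Z"].to_numpy() ** 2
    fail = chisq > max_chisq
    counts["chisq"] = int(fail.sum())
    keep &= ~fail
    for col, thr, name in (("MAF", min_maf, "maf"), ("INFO", min_info, "info")):
        if thr is None:
            continue
        if col not in df.columns:
            logger.warning("qc_filter[%s]: no %s column; %s filter skipped",
                           table.trait, col, name)
            continue
        fail = df[col].to_numpy() < thr
        counts[name] = int(fail.sum())
        keep &= ~fail
    for name, c in counts.items():
        if c:
            logger.info("qc_filter[%s]: removed %d record(s) failing %s",
                        table.trait, c, name)
    return SumstatsTable(data=df[keep].reset_index(drop=True), trait=table.trait,
                         population=table.population,
                         log={**table.log, "qc": counts})


def expected_chisq_tail(max_chisq: float) -> float:
    """Null expectation of the fraction removed by the chi-square filter."""
    return float(_stats.chi2.sf(max_chisq, df=1))


def merge_panel(tables: list, ld_panels: dict, n_blocks: int = 200,
                block_map: np.ndarray = None) -> HarmonizedPanel:
    """Intersect harmonized tables with LD panels into an aligned panel.

    ``ld_panels`` maps context keys (population label, or a sorted
    tuple of two labels) to :class:`LdScorePanel`.  Variants are sorted
    lexicographically by id; jackknife blocks are contiguous runs in
    that ordering unless ``block_map`` (per-variant ids, aligned to the
    sorted intersection) is given.
    """
    if not tables:
        raise ValueError("need at least one table")
    pops = [t.population for t in tables]
    needed = {context_key(p, q) for p in pops for q in pops}
    missing = [k for k in needed if k not in ld_panels]
    if missing:
        raise KeyError(f"LD panel missing required context(s): {missing}")

    common = None
    for tab in tables:
        ids = set(tab.data["SNP"])
        common = ids if common is None else (common & ids)
    for key in needed:
        common &= set(ld_panels[key].table["SNP"])
    if not common:
        raise ValueError("empty variant intersection across tables and LD panels")
    order = np.array(sorted(common))

    M = len(order)
    T = len(tables)
    z = np.empty((M, T))
    n = np.empty(T)
    for j, tab in enumerate(tables):
        sub = tab.data.set_index("SNP").loc[order]
        z[:, j] = sub["Z"].to_numpy()
        n[j] = float(sub["N"].median())
    ld = {}
    m_ref = {}
    for key in needed:
        panel = ld_panels[key]
        ld[key] = panel.table.set_index("SNP").loc[order, "L2"].to_numpy()
        m_ref[key] = panel.m_ref
    if block_map is None:
        block_map = default_blocks(M, min(n_blocks, M))
    return HarmonizedPanel(
        snp=order, z=z, n=n,
        traits=[t.trait for t in tables],
        populations=pops,
        ld=ld, m_ref=m_ref, blocks=block_map,
    )
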