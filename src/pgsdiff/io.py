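"""Tab-separated readers, writers and allele harmonization.

All formats are plain TSV.  Summary statistics follow common GWAS
conventions with auto-detected column headers (override with an explicit
``column_map``); frequency tables carry variant ID, effect allele and
frequency; posterior-sample matrices have variant IDs in the first column
and one column per posterior draw.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import FREQ_TOL, PopulationPanel, SummaryStats

__all__ = [
    "HarmonizedDataset",
    "read_sumstats",
    "read_frequencies",
    "read_posterior_samples",
    "harmonize",
    "write_result_tsv",
]

logger = logging.getLogger("pgsdiff")
if not logger.handlers:  # default to stderr logging, library-friendly level
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

# candidate headers, lower-cased, for auto-detection
_COLUMN_CANDIDATES = {
    "id": ["snp", "id", "rsid", "variant_id", "markername", "variant"],
    "ea": ["a1", "ea", "effect_allele", "allele1"],
    "oa": ["a2", "oa", "other_allele", "allele2", "allele0"],
    "beta": ["beta", "b", "effect", "beta_gwas"],
    "se": ["se", "stderr", "standard_error"],
    "n": ["n", "n_eff", "neff", "samplesize"],
    "freq": ["frq", "eaf", "freq", "maf", "af", "effect_allele_frequency"],
}

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _resolve_columns(
    columns: list[str], column_map: dict[str, str] | None, required: list[str]
) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    column_map = column_map or {}
    for role in _COLUMN_CANDIDATES:
        if role in column_map:
            if column_map[role] not in columns:
                raise ValueError(
                    f"column_map names {column_map[role]!r} for {role!r} but the "
                    f"file has columns {columns}"
                )
            resolved[role] = column_map[role]
            continue
        for cand in _COLUMN_CANDIDATES[role]:
            if cand in lower:
                resolved[role] = lower[cand]
                break
    missing = [r for r in required if r not in resolved]
    if missing:
        raise ValueError(
            f"could not resolve required column(s) {missing}; file has columns "
            f"{columns}; candidates tried: "
            + "; ".join(f"{m}: {_COLUMN_CANDIDATES[m]}" for m in missing)
        )
    return resolved


@dataclass(frozen=True)
class HarmonizedDataset:
    """Summary statistics and two frequency vectors on a shared SNP set.

    ``flags`` records per-variant provenance: ``kept`` or ``sign_flipped``
    for retained SNPs (dropped SNPs appear only in the reader logs).
    """

    ids: np.ndarray
    ea: np.ndarray
    oa: np.ndarray
    beta_hat: np.ndarray
    s2: np.ndarray
    f: np.ndarray
    g: np.ndarray
    flags: np.ndarray

    @property
    def M(self) -> int:
        return self.ids.shape[0]

    def panel(self) -> PopulationPanel:
        return PopulationPanel(f=self.f, g=self.g)

    def stats(self, N_eff: int | None = None) -> SummaryStats:
        return SummaryStats(beta_hat=self.beta_hat, s2=self.s2, N_eff=N_eff)


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV.

    Requires ID, effect allele, other allele and beta columns, plus either
    a standard-error column (``s2 = SE^2``) or sample-size and frequency
    columns (``s2 = 1/(2 N f (1-f))``).  Rows with missing or invalid
    fields are dropped with a logged reason.

    Returns a DataFrame with normalized columns
    ``id, ea, oa, beta, s2`` (+ ``freq`` and ``n`` when present).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = _resolve_columns(list(df.columns), column_map, ["id", "ea", "oa", "beta"])
    if "se" not in cols and not ("n" in cols and "freq" in cols):
        raise ValueError(
            "summary statistics need either an SE column or both N and "
            f"frequency columns; resolved {sorted(cols)} from {list(df.columns)}"
        )
    out = pd.DataFrame(
        {
            "id": df[cols["id"]].astype(str),
            "ea": df[cols["ea"]].astype(str).str.upper(),
            "oa": df[cols["oa"]].astype(str).str.upper(),
            "beta": pd.to_numeric(df[cols["beta"]], errors="coerce"),
        }
    )
    if "freq" in cols:
        out["freq"] = pd.to_numeric(df[cols["freq"]], errors="coerce")
    if "n" in cols:
        out["n"] = pd.to_numeric(df[cols["n"]], errors="coerce")
    if "se" in cols:
        se = pd.to_numeric(df[cols["se"]], errors="coerce")
        out["s2"] = se**2
        bad = out["beta"].isna() | se.isna() | (se <= 0)
    else:
        freq_ok = (out["freq"] > FREQ_TOL) & (out["freq"] < 1 - FREQ_TOL)
        bad = out["beta"].isna() | out["freq"].isna() | out["n"].isna() | ~freq_ok
        out["s2"] = np.nan
        ok = ~bad
        out.loc[ok, "s2"] = 1.0 / (
            2.0 * out.loc[ok, "n"] * out.loc[ok, "freq"] * (1.0 - out.loc[ok, "freq"])
        )
    n_bad = int(bad.sum())
    if n_bad:
        for vid in out.loc[bad, "id"].head(10):
            logger.warning("dropping %s: missing or invalid beta/SE/N/frequency", vid)
        if n_bad > 10:
            logger.warning("... and %d more rows dropped", n_bad - 10)
    return out.loc[~bad].reset_index(drop=True)


def read_frequencies(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a per-population allele-frequency TSV (ID, effect allele, freq)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = _resolve_columns(list(df.columns), column_map, ["id", "ea", "freq"])
    out = pd.DataFrame(
        {
            "id": df[cols["id"]].astype(str),
            "ea": df[cols["ea"]].astype(str).str.upper(),
            "freq": pd.to_numeric(df[cols["freq"]], errors="coerce"),
        }
    )
    if "oa" in cols:
        out["oa"] = df[cols["oa"]].astype(str).str.upper()
    bad = out["freq"].isna() | (out["freq"] < FREQ_TOL) | (out["freq"] > 1 - FREQ_TOL)
    if bad.any():
        logger.warning("dropping %d rows with missing/extreme frequencies", int(bad.sum()))
    return out.loc[~bad].reset_index(drop=True)


def read_posterior_samples(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a posterior-sample matrix (rows = SNPs, first column = ID)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    ids = df.iloc[:, 0].astype(str).to_numpy()
    samples = df.iloc[:, 1:].to_numpy(dtype=float)
    if samples.shape[1] < 2:
        raise ValueError("posterior-sample matrix needs at least 2 sample columns")
    return ids, samples


def harmonize(
    sumstats: pd.DataFrame,
    freq1: pd.DataFrame,
    freq2: pd.DataFrame,
    *,
    drop_ambiguous: bool = True,
) -> HarmonizedDataset:
    """Join summary statistics with two frequency tables on variant ID.

    The effect-allele coding of the summary statistics is the reference.
    Frequency rows whose effect allele matches the summary-stat *other*
    allele are complemented (``freq -> 1 - freq``); strand-ambiguous SNPs
    (A/T, C/G) and allele mismatches are dropped with logged reasons.  The
    output is ordered by sorted variant ID.
    """
    ss = sumstats.set_index("id")
    f1 = freq1.set_index("id")
    f2 = freq2.set_index("id")
    common = sorted(set(ss.index) & set(f1.index) & set(f2.index))
    if not common:
        raise ValueError("no variants shared by all three inputs")

    ids, eas, oas, betas, s2s, fs, gs, flags = [], [], [], [], [], [], [], []
    n_drop_ambig = n_drop_mismatch = 0
    for vid in common:
        row = ss.loc[vid]
        ea, oa = row["ea"], row["oa"]
        if drop_ambiguous and (ea, oa) in _AMBIGUOUS:
            n_drop_ambig += 1
            logger.debug("dropping %s: strand_ambiguous", vid)
            continue
        freqs = []
        ok = True
        for tab in (f1, f2):
            frow = tab.loc[vid]
            if frow["ea"] == ea:
                freqs.append(float(frow["freq"]))
            elif frow["ea"] == oa:
                freqs.append(1.0 - float(frow["freq"]))
            else:
                ok = False
                break
        if not ok:
            n_drop_mismatch += 1
            logger.debug("dropping %s: allele_mismatch", vid)
            continue
        ids.append(vid)
        eas.append(ea)
        oas.append(oa)
        betas.append(float(row["beta"]))
        s2s.append(float(row["s2"]))
        fs.append(freqs[0])
        gs.append(freqs[1])
        flags.append("kept")
    if n_drop_ambig:
        logger.info("harmonize: dropped %d strand-ambiguous SNPs", n_drop_ambig)
    if n_drop_mismatch:
        logger.info("harmonize: dropped %d allele-mismatched SNPs", n_drop_mismatch)
    if not ids:
        raise ValueError("harmonization left no usable variants")
    # frequency complementing counts as a sign-consistent flip of coding
    flipped = [
        "sign_flipped" if (f1.loc[v]["ea"] != e) else fl
        for v, e, fl in zip(ids, eas, flags)
    ]
    return HarmonizedDataset(
        ids=np.array(ids),
        ea=np.array(eas),
        oa=np.array(oas),
        beta_hat=np.array(betas),
        s2=np.array(s2s),
        f=np.array(fs),
        g=np.array(gs),
        flags=np.array(flipped),
    )


def write_result_tsv(path: str | Path, rows: pd.DataFrame, header_comment: str = "") -> None:
    """Write a results table as TSV with an optional ``#`` header line."""
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        rows.to_csv(fh, sep="\t", index=False, float_format="%.10g")
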