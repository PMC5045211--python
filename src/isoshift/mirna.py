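"""miRNA seed-site counting and enrichment in tandem-UTR extensions.

Seed sites follow the canonical grading on the mRNA sense strand, given a
miRNA with seed region nt 2-8:

* ``8mer``    — reverse complement of nt 2-8 followed by ``A``;
* ``7mer-m8`` — reverse complement of nt 2-8 (no trailing ``A``);
* ``7mer-1A`` — reverse complement of nt 2-7 followed by ``A`` (and not part
  of an 8mer).

Overlapping matches each count; a position matching a longer type is not
double-counted as its nested shorter types.  Ambiguous bases (N) never match
but count toward region length.

Per-miRNA enrichment compares the site density in significantly-shortened
UTR extensions against resampled sets of unchanged extensions matched on
length and GC content; the empirical p-value uses the plus-one estimator and
significance requires BH q <= 10% and fold >= 1.5.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "seed_patterns",
    "count_seed_sites",
    "expressed_mirnas",
    "density_by_class",
    "mirna_enrichment",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def seed_patterns(mature: str) -> dict[str, str]:
    """Site sequences for a mature miRNA: 8mer, 7mer-m8 and 7mer-1A."""
    dna = _dna(mature)
    if len(dna) < 8:
        raise ValueError("mature miRNA must be at least 8 nt")
    if set(dna) - set("ACGT"):
        raise ValueError("miRNA sequence must be over A/C/G/U(T)")
    rc7 = _revcomp(dna[1:8])      # reverse complement of nt 2-8
    rc6 = _revcomp(dna[1:7])      # reverse complement of nt 2-7 == rc7[1:]
    return {"8mer": rc7 + "A", "7mer-m8": rc7, "7mer-1A": rc6 + "A"}


def _find_all(seq: str, pat: str) -> list[int]:
    out, i = [], seq.find(pat)
    while i != -1:
        out.append(i)
        i = seq.find(pat, i + 1)
    return out


def count_seed_sites(sequence: str, mature: str) -> dict[str, int]:
    """Seed-site counts by type for one miRNA in one sense-strand sequence."""
    seq = _dna(sequence)
    pats = seed_patterns(mature)
    rc7 = pats["7mer-m8"]
    n8 = m8 = a1 = 0
    for i in _find_all(seq, rc7):
        if seq[i + 7: i + 8] == "A":
            n8 += 1
        else:
            m8 += 1
    for j in _find_all(seq, pats["7mer-1A"]):
        if j == 0 or seq[j - 1] != rc7[0]:
            a1 += 1
    return {"8mer": n8, "7mer-m8": m8, "7mer-1A": a1, "total": n8 + m8 + a1}


def expressed_mirnas(mirnas: pd.DataFrame, min_expression: float = 1.0) -> pd.DataFrame:
    """Subset of the miRNA table passing the expression floor.

    Expressed means mean normalized count >= ``min_expression`` in any
    ``expr_*`` column; without expression columns all miRNAs are kept.
    """
    expr_cols = [c for c in mirnas.columns if c.startswith("expr")]
    if not expr_cols:
        return mirnas.copy()
    keep = (mirnas[expr_cols] >= min_expression).any(axis=1)
    return mirnas[keep].reset_index(drop=True)


def _site_count_matrix(seqs: list[str], mirnas: pd.DataFrame) -> np.ndarray:
    """regions x miRNAs matrix of total seed-site counts."""
    out = np.zeros((len(seqs), len(mirnas)), dtype=float)
    for j, mature in enumerate(mirnas["sequence"]):
        pats = seed_patterns(mature)
        rc7, a1p = pats["7mer-m8"], pats["7mer-1A"]
        for i, seq in enumerate(seqs):
            n = 0
            for pos in _find_all(seq, rc7):
                n += 1
            for pos in _find_all(seq, a1p):
                if pos == 0 or seq[pos - 1] != rc7[0]:
                    n += 1
            out[i, j] = n
    return out


def density_by_class(regions: pd.DataFrame, mirnas: pd.DataFrame, *,
                     min_expression: float = 1.0, min_per_class: int = 10):
    """Per-region site density (expressed miRNAs) and class comparisons.

    Density = summed seed sites over expressed miRNAs / region length,
    computed separately for extensions and cores.  Returns
    ``(per_region, tests)`` with Mann-Whitney comparisons of
    shortened_significant vs unchanged, separately for extensions and cores.
    Zero-length regions are excluded and logged.
    """
    mset = expressed_mirnas(mirnas, min_expression)
    per_region = regions[["event_id", "sig_class"]].copy()
    for part in ("ext", "core"):
        seqs = regions[f"{part}_seq"].fillna("").tolist()
        lengths = np.array([len(s) for s in seqs], float)
        if mset.empty:
            dens = np.zeros(len(seqs))
        else:
            counts = _site_count_matrix(seqs, mset).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                dens = np.where(lengths > 0, counts / np.where(lengths > 0, lengths, 1), np.nan)
        n_zero = int((lengths == 0).sum())
        if n_zero:
            logger.info("density_by_class: %d zero-length %s regions excluded", n_zero, part)
        per_region[f"{part}_density"] = dens
    tests = {}
    for part in ("ext", "core"):
        sig = per_region.loc[per_region["sig_class"] == "shortened_significant",
                             f"{part}_density"].dropna()
        unc = per_region.loc[per_region["sig_class"] == "unchanged",
                             f"{part}_density"].dropna()
        if len(sig) >= min_per_class and len(unc) >= min_per_class:
            u = stats.mannwhitneyu(sig, unc, alternative="two-sided")
            tests[part] = {"median_significant": float(sig.median()),
                           "median_unchanged": float(unc.median()),
                           "p_value": float(u.pvalue)}
        else:
            tests[part] = {"p_value": float("nan"),
                           "reason": f"fewer than {min_per_class} regions in a class"}
    return per_region, tests


def mirna_enrichment(regions: pd.DataFrame, mirnas: pd.DataFrame, *,
                     n_resamples: int = 1000, gc_tolerance: float = 0.02,
                     len_tolerance: float = 0.20, seed: int | None = None,
                     fdr: float = 0.10, min_fold: float = 1.5,
                     min_expression: float = 1.0, max_relaxations: int = 5) -> pd.DataFrame:
    """Per-miRNA seed-site enrichment in significantly shortened extensions.

    The foreground is the extension sequences of ``shortened_significant``
    UTRs; the null draws, ``n_resamples`` times, one unchanged-class
    extension per foreground region matched on length (within
    ``len_tolerance`` relative) and GC (within ``gc_tolerance`` absolute),
    doubling both tolerances with a logged warning when a region has no
    match (up to ``max_relaxations`` times; a region that still has no match
    is dropped with a logged reason).

    fold = observed density / mean null density;
    empirical p = (1 + #{null >= observed}) / (n_resamples + 1);
    significant requires BH q <= ``fdr`` AND fold >= ``min_fold``.
    """
    rng = np.random.default_rng(seed)
    mset = expressed_mirnas(mirnas, min_expression)
    fg = regions[regions["sig_class"] == "shortened_significant"]
    bg = regions[regions["sig_class"] == "unchanged"]
    empty_cols = ["mirna_id", "observed_density", "expected_density", "fold",
                  "p_value", "n_foreground", "q_value", "significant"]
    if fg.empty:
        logger.info("mirna_enrichment: no shortened_significant regions; nothing to test")
        return pd.DataFrame(columns=empty_cols)
    if len(bg) < len(fg):
        raise ValueError("background (unchanged) pool smaller than foreground")

    def gc_frac(s: str) -> float:
        return (s.count("G") + s.count("C")) / len(s) if s else float("nan")

    fg_seqs = fg["ext_seq"].tolist()
    bg_seqs = bg["ext_seq"].tolist()
    fg_len = np.array([len(s) for s in fg_seqs], float)
    bg_len = np.array([len(s) for s in bg_seqs], float)
    fg_gc = np.array([gc_frac(s) for s in fg_seqs])
    bg_gc = np.array([gc_frac(s) for s in bg_seqs])

    candidates, kept = [], []
    for i in range(len(fg_seqs)):
        gt, lt = gc_tolerance, len_tolerance
        for _ in range(max_relaxations + 1):
            ok = np.where((np.abs(bg_len - fg_len[i]) <= lt * fg_len[i])
                          & (np.abs(bg_gc - fg_gc[i]) <= gt))[0]
            if ok.size:
                break
            gt, lt = gt * 2, lt * 2
            logger.warning("matching stratum exhausted for region %s; relaxing "
                           "tolerances to gc=%.3f len=%.2f", fg.iloc[i]["event_id"], gt, lt)
        if ok.size:
            candidates.append(ok)
            kept.append(i)
        else:
            logger.warning("region %s dropped: no matchable background after "
                           "maximal relaxation", fg.iloc[i]["event_id"])
    if not kept:
        raise ValueError("no foreground regions with matchable background")

    fg_counts = _site_count_matrix([fg_seqs[i] for i in kept], mset)
    bg_counts = _site_count_matrix(bg_seqs, mset)
    total_fg_len = fg_len[kept].sum()
    obs_density = fg_counts.sum(axis=0) / total_fg_len

    null_density = np.empty((n_resamples, len(mset)))
    for b in range(n_resamples):
        picks = np.array([c[rng.integers(c.size)] for c in candidates])
        null_density[b] = bg_counts[picks].sum(axis=0) / bg_len[picks].sum()

    mean_null = null_density.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean_null > 0, obs_density / mean_null, np.nan)
    p_emp = (1 + (null_density >= obs_density[None, :]).sum(axis=0)) / (n_resamples + 1)
    out = pd.DataFrame({
        "mirna_id": mset["mirna_id"].to_numpy(),
        "observed_density": obs_density,
        "expected_density": mean_null,
        "fold": fold,
        "p_value": p_emp,
        "n_foreground": len(kept),
    })
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = (out["q_value"] <= fdr) & (out["fold"] >= min_fold)
    return out
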