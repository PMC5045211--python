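"""Synthetic-data generator with recorded ground truth.

Emulates a paired infection study: ``n_individuals`` donors sampled in two
conditions (control / infected), genes with 2-10 isoforms whose usage follows
a Dirichlet distribution, per-event inclusion/exclusion read counts with
planted PSI shifts (including a tandem-UTR category where ~95% of true shifts
are negative, i.e. 3'UTR shortening), UTR core/extension sequences with
planted miRNA seed sites at a controlled fold enrichment, per-individual
expression fold changes correlated with delta-PSI at a target Spearman rho,
and 3'-end read positions around the two polyadenylation sites.

All randomness flows from a single integer seed; per-stage sub-streams are
derived with ``numpy.random.SeedSequence`` spawn keys so that outputs of one
stage are stable when another stage's parameters change.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("AFE", "ALE", "RI", "SE", "TandemUTR")

#: inclusion isoform = longer isoform for RI/SE/TandemUTR -> longer
#: informative region for inclusion reads in those categories.
INCLUSION_LENGTH = {"AFE": 1.0, "ALE": 1.0, "RI": 2.0, "SE": 1.0, "TandemUTR": 2.0}

# Synthetic mature miRNA sequences (RNA alphabet, 21 nt).  These are invented
# sequences, not real miRBase entries.  Seed regions (nt 2-8) carry 1-3 G/C
# bases, in the range typical of mammalian seeds, so that background site
# densities are high enough for stable density estimation yet GC-dependent
# enough to exercise composition matching.
DEFAULT_MIRNAS = {
    "syn-mir-01": "UAAUACUUCACAGAACUUUGU",  # seed AAUACUU, 1 GC
    "syn-mir-02": "UUGUAAACGACAUGAUGGUUU",  # seed UGUAAAC, 2 GC
    "syn-mir-03": "UAUUGCACUCUGAGCUUGGCA",  # seed AUUGCAC, 3 GC
    "syn-mir-04": "UAGUGUUACCUCGACUGGAAG",  # seed AGUGUUA, 2 GC
    "syn-mir-05": "UUCAAUUGACCCUUUAACCUG",  # seed UCAAUUG, 2 GC
    "syn-mir-06": "UAGCUUAUCAGACUGAUGUUG",  # seed AGCUUAU, 2 GC
    "syn-mir-07": "UGAAUGUUGAAUUCCAUGGGU",  # seed GAAUGUU, 2 GC
    "syn-mir-08": "UAUGCAUUGUCCCUUAACUGU",  # seed AUGCAUU, 2 GC
}

_STREAMS = {
    "isoforms": 0,
    "events": 1,
    "utr": 2,
    "expression": 3,
    "threeprime": 4,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Sub-stream generator keyed by the global seed and a stage name."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Stated world of the synthetic study.

    Defaults emulate the study design: 60 paired donors, two conditions,
    moderate Dirichlet concentration for isoform usage, planted usage shifts
    of 0.15, planted |delta PSI| of 0.2 at ~200 reads per event, a tandem-UTR
    category where 95% of true shifts are toward the proximal polyA site
    (negative delta PSI) and a skipped-exon category where 80% are toward
    inclusion, 3-fold planted seed enrichment for one miRNA, and a target
    Spearman correlation of 0.6 between delta PSI and expression fold change.
    """

    n_individuals: int = 60
    # isoform usage
    n_genes: int = 200
    isoforms_per_gene: tuple[int, int] = (2, 10)
    dirichlet_concentration: float = 10.0
    frac_diu: float = 0.1
    usage_effect: float = 0.15
    gene_tpm_log_mean: float = math.log(100.0)
    gene_tpm_log_sd: float = 1.0
    sample_tpm_log_sd: float = 0.3
    # events
    n_events_per_category: dict[str, int] = field(
        default_factory=lambda: {"AFE": 80, "ALE": 80, "RI": 80, "SE": 120, "TandemUTR": 120}
    )
    read_depth_per_event: float = 200.0
    frac_events_shifted: float = 0.3
    delta_psi_magnitude: float = 0.2
    frac_negative: dict[str, float] = field(
        default_factory=lambda: {"AFE": 0.5, "ALE": 0.7, "RI": 0.5, "SE": 0.2, "TandemUTR": 0.95}
    )
    psi_base_range: tuple[float, float] = (0.3, 0.7)
    psi_indiv_sd: float = 0.05
    #: sd of a shared per-donor multiplier on planted shifts (0 = none);
    #: > 0 creates correlated global shifts across events and categories
    individual_effect_sd: float = 0.0
    # UTR sequences
    utr_core_len: int = 500
    utr_ext_len: int = 2000
    mirna_sequences: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MIRNAS))
    planted_mirnas: tuple[str, ...] = ("syn-mir-01",)
    planted_fold: float = 3.0
    gc_strata: tuple[float, float] = (0.4, 0.6)
    p_high_gc_significant: float = 0.5
    p_high_gc_unchanged: float = 0.5
    # expression linkage
    rho_dpsi_fc: float = 0.6
    fc_slope: float = 2.0
    null_fc_sd: float = 0.5
    # 3'-end reads (validation assay on a donor subset, as in targeted
    # 3'-seq follow-up designs)
    depth_threeprime: float = 500.0
    jitter_sd: float = 10.0
    n_individuals_threeprime: int = 6
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_diu": self.frac_diu,
            "frac_events_shifted": self.frac_events_shifted,
            "p_high_gc_significant": self.p_high_gc_significant,
            "p_high_gc_unchanged": self.p_high_gc_unchanged,
            **{f"frac_negative[{k}]": v for k, v in self.frac_negative.items()},
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name, v in (
            ("n_individuals", self.n_individuals),
            ("n_genes", self.n_genes),
            ("utr_core_len", self.utr_core_len),
        ):
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.utr_ext_len < 0:
            raise ConfigError("utr_ext_len must be non-negative")
        lo, hi = self.isoforms_per_gene
        if lo < 1 or hi < lo:
            raise ConfigError(f"invalid isoforms_per_gene range {self.isoforms_per_gene}")
        if self.frac_diu > 0 and lo < 2:
            raise ConfigError("DIU genes need at least 2 isoforms; raise isoforms_per_gene[0]")
        if not 0.0 < self.delta_psi_magnitude < 1.0:
            raise ConfigError("delta_psi_magnitude must be in (0, 1)")
        if self.dirichlet_concentration <= 0:
            raise ConfigError("dirichlet_concentration must be positive")
        if self.planted_fold < 1.0:
            raise ConfigError("planted_fold must be >= 1 (use 1 for a null simulation)")
        if abs(self.rho_dpsi_fc) > 0.99:
            raise ConfigError("|rho_dpsi_fc| must be <= 0.99")
        for cat in self.n_events_per_category:
            if cat not in CATEGORIES:
                raise ConfigError(f"unknown event category {cat!r}")
        for mid, seq in self.mirna_sequences.items():
            s = seq.upper().replace("U", "T")
            if len(s) < 8 or set(s) - set("ACGT"):
                raise ConfigError(f"miRNA {mid} must be >= 8 nt over A/C/G/U(T)")
        for mid in self.planted_mirnas:
            if mid not in self.mirna_sequences:
                raise ConfigError(f"planted miRNA {mid} not in mirna_sequences")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["isoforms_per_gene"] = list(self.isoforms_per_gene)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("isoforms_per_gene", "gc_strata", "planted_mirnas", "psi_base_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted parameters, sufficient to score recovery without re-simulation."""

    genes: pd.DataFrame | None = None            # gene_id, K, is_diu, effect, prop_ni, prop_inf
    events: pd.DataFrame | None = None           # event_id, category, gene_id, is_shifted, psi_base, delta_planted
    event_individual: pd.DataFrame | None = None # event_id, individual_id, psi_ni, psi_inf, delta_psi
    utrs: pd.DataFrame | None = None             # event_id, sig_class, gc, planted site counts
    expression: pd.DataFrame | None = None       # gene_id, event_id, linked, target_rho

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        out = SyntheticTruth()
        for f in dataclasses.fields(SyntheticTruth):
            mine, theirs = getattr(self, f.name), getattr(other, f.name)
            setattr(out, f.name, theirs if theirs is not None else mine)
        return out

    def to_json(self, path) -> None:
        blob = {}
        for f in dataclasses.fields(SyntheticTruth):
            df = getattr(self, f.name)
            blob[f.name] = None if df is None else df.to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            blob = json.load(fh)
        out = cls()
        for name, data in blob.items():
            if data is not None:
                setattr(out, name, pd.DataFrame(data))
        return out


def sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Paired sample sheet: one control and one infected sample per donor."""
    rows = []
    for i in range(config.n_individuals):
        ind = f"ind{i:03d}"
        rows.append((f"{ind}_ctl", ind, "control"))
        rows.append((f"{ind}_inf", ind, "infected"))
    return pd.DataFrame(rows, columns=["sample_id", "individual_id", "condition"])


# ---------------------------------------------------------------------------
# isoform usage
# ---------------------------------------------------------------------------

def simulate_isoform_matrix(config: SimulationConfig):
    """Isoform-level TPM matrix with planted differential usage.

    Null genes draw sample-wise proportions from one Dirichlet in both
    conditions; DIU genes shift the condition mean by ``usage_effect`` in one
    component (moved to another), so the planted effect size (max |difference|
    in mean proportion) equals ``usage_effect`` exactly.

    Returns ``(quant, sheet, truth)`` where ``quant`` is a wide DataFrame
    indexed by isoform_id with a ``gene_id`` column plus one TPM column per
    sample.
    """
    config.validate()
    rng = _rng(config.seed, "isoforms")
    sheet = sample_sheet(config)
    n = config.n_individuals
    lo, hi = config.isoforms_per_gene
    a0 = config.dirichlet_concentration
    e = config.usage_effect

    n_diu = int(round(config.frac_diu * config.n_genes))
    diu_idx = set(rng.choice(config.n_genes, size=n_diu, replace=False).tolist()) if n_diu else set()

    iso_rows, tpm_blocks = [], []
    truth_rows = []
    sample_ids = sheet["sample_id"].tolist()
    ctl_cols = [s for s in sample_ids if s.endswith("_ctl")]
    inf_cols = [s for s in sample_ids if s.endswith("_inf")]

    for g in range(config.n_genes):
        gene_id = f"g{g:04d}"
        K = int(rng.integers(lo, hi + 1))
        is_diu = g in diu_idx
        if is_diu and K < 2:
            raise ConfigError(f"gene {gene_id}: DIU planted but only {K} isoform(s)")
        # mean usage; for DIU genes resample until the donor component can
        # give away the full effect without going negative
        while True:
            m = rng.dirichlet(np.ones(K))
            if not is_diu or m.max() >= e + 0.02:
                break
        m_ctl = m
        if is_diu:
            m_inf = m.copy()
            j_hi, j_lo = int(np.argmax(m)), int(np.argmin(m))
            if j_hi == j_lo:  # K==1 is excluded above; ties cannot collide for K>=2
                j_lo = (j_hi + 1) % K
            m_inf[j_hi] -= e
            m_inf[j_lo] += e
        else:
            m_inf = m

        p_ctl = rng.dirichlet(a0 * np.clip(m_ctl, 1e-3, None), size=n)   # n x K
        p_inf = rng.dirichlet(a0 * np.clip(m_inf, 1e-3, None), size=n)
        base = float(rng.lognormal(config.gene_tpm_log_mean, config.gene_tpm_log_sd))
        g_tpm_ctl = base * rng.lognormal(0.0, config.sample_tpm_log_sd, size=n)
        g_tpm_inf = base * rng.lognormal(0.0, config.sample_tpm_log_sd, size=n)

        tpm = np.empty((K, 2 * n))
        tpm[:, 0::2] = (p_ctl * g_tpm_ctl[:, None]).T  # interleave ctl/inf per donor
        tpm[:, 1::2] = (p_inf * g_tpm_inf[:, None]).T
        tpm_blocks.append(tpm)
        for k in range(K):
            iso_rows.append((f"{gene_id}.i{k}", gene_id))
        truth_rows.append(
            dict(gene_id=gene_id, K=K, is_diu=bool(is_diu),
                 effect=float(e if is_diu else 0.0),
                 prop_ctl=[float(x) for x in m_ctl],
                 prop_inf=[float(x) for x in m_inf])
        )

    cols = [c for pair in zip(ctl_cols, inf_cols) for c in pair]
    quant = pd.DataFrame(np.vstack(tpm_blocks), columns=cols,
                         index=pd.Index([r[0] for r in iso_rows], name="isoform_id"))
    quant.insert(0, "gene_id", [r[1] for r in iso_rows])
    quant = quant[["gene_id"] + sample_ids]
    truth = SyntheticTruth(genes=pd.DataFrame(truth_rows))
    return quant, sheet, truth


# ---------------------------------------------------------------------------
# splicing events
# ---------------------------------------------------------------------------

def simulate_event_counts(config: SimulationConfig):
    """Per-event inclusion/exclusion counts with planted PSI shifts.

    Totals are Poisson(read_depth_per_event); inclusion reads are Binomial
    with a length-weighted inclusion probability so that the length-adjusted
    PSI estimator is unbiased.  Shifted events move PSI by
    ``delta_psi_magnitude`` with a sign that is negative with the per-category
    ``frac_negative`` probability; per-individual true PSI values get
    Normal(0, psi_indiv_sd) donor effects.

    Returns ``(events, annotations, sheet, truth)``: a long counts table
    (one row per event x sample), a BED-convention annotation table, the
    sample sheet, and the truth.
    """
    config.validate()
    rng = _rng(config.seed, "events")
    sheet = sample_sheet(config)
    n = config.n_individuals
    individuals = [f"ind{i:03d}" for i in range(n)]
    lo_psi, hi_psi = config.psi_base_range

    # shared donor multiplier on planted shifts (one draw per donor)
    donor_factor = 1.0 + rng.normal(0.0, config.individual_effect_sd, size=n) \
        if config.individual_effect_sd > 0 else np.ones(n)

    ev_rows, ann_rows, truth_ev, truth_ind = [], [], [], []
    for cat in CATEGORIES:
        n_ev = int(config.n_events_per_category.get(cat, 0))
        if n_ev == 0:
            continue
        n_shift = int(round(config.frac_events_shifted * n_ev))
        shifted = np.zeros(n_ev, bool)
        shifted[rng.choice(n_ev, size=n_shift, replace=False)] = True
        psi_base = rng.uniform(lo_psi, hi_psi, size=n_ev)
        neg = rng.random(n_ev) < config.frac_negative.get(cat, 0.5)
        delta = np.where(shifted, np.where(neg, -1.0, 1.0) * config.delta_psi_magnitude, 0.0)
        psi_inf_target = np.clip(psi_base + delta, 0.01, 0.99)
        delta = psi_inf_target - psi_base  # record post-truncation value

        l_inc = INCLUSION_LENGTH[cat]
        l_exc = 1.0
        for j in range(n_ev):
            event_id = f"{cat}_{j:04d}"
            gene_id = f"eg_{cat}_{j:04d}"
            chrom = f"chr{1 + (len(ann_rows) % 22)}"
            start = int(rng.integers(10_000, 1_000_000))
            strand = "+" if rng.random() < 0.5 else "-"
            ann_rows.append((event_id, cat, gene_id, chrom, start, start + 1000, strand))

            psi_ni_i = np.clip(psi_base[j] + rng.normal(0, config.psi_indiv_sd, n), 0.01, 0.99)
            psi_inf_i = np.clip(psi_ni_i + delta[j] * donor_factor
                                + rng.normal(0, config.psi_indiv_sd, n), 0.01, 0.99)
            for cond, psi_i in (("control", psi_ni_i), ("infected", psi_inf_i)):
                totals = rng.poisson(config.read_depth_per_event, size=n)
                # read allocation is proportional to isoform share x region length
                p_inc = psi_i * l_inc / (psi_i * l_inc + (1 - psi_i) * l_exc)
                inc = rng.binomial(totals, p_inc)
                exc = totals - inc
                suffix = "ctl" if cond == "control" else "inf"
                for i in range(n):
                    ev_rows.append((event_id, cat, gene_id, f"{individuals[i]}_{suffix}",
                                    int(inc[i]), int(exc[i]), l_inc, l_exc))
            truth_ev.append(dict(event_id=event_id, category=cat, gene_id=gene_id,
                                 is_shifted=bool(shifted[j]), psi_base=float(psi_base[j]),
                                 delta_planted=float(delta[j])))
            for i in range(n):
                truth_ind.append((event_id, individuals[i], float(psi_ni_i[i]),
                                  float(psi_inf_i[i]), float(psi_inf_i[i] - psi_ni_i[i])))

    events = pd.DataFrame(ev_rows, columns=["event_id", "category", "gene_id", "sample_id",
                                            "inc_count", "exc_count", "inc_len", "exc_len"])
    annotations = pd.DataFrame(ann_rows, columns=["event_id", "category", "gene_id",
                                                  "chrom", "start", "end", "strand"])
    truth = SyntheticTruth(
        events=pd.DataFrame(truth_ev),
        event_individual=pd.DataFrame(truth_ind, columns=["event_id", "individual_id",
                                                          "psi_ni", "psi_inf", "delta_psi"]),
    )
    return events, annotations, sheet, truth


# ---------------------------------------------------------------------------
# UTR sequences
# ---------------------------------------------------------------------------

def _rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _base_probs(gc: float) -> dict[str, float]:
    return {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}


def expected_site_density(mature: str, gc: float) -> float:
    """Expected per-nucleotide total seed-site density in i.i.d. sequence.

    Sites: 7mer-m8 / 8mer share the reverse complement of miRNA nt 2-8
    (``rc7``); a 7mer-1A is rc7[1:] + 'A' not preceded by rc7[0].
    """
    dna = _rna_to_dna(mature)
    rc7 = _revcomp(dna[1:8])
    p = _base_probs(gc)

    def pstr(s: str) -> float:
        out = 1.0
        for c in s:
            out *= p[c]
        return out

    return pstr(rc7) + (1.0 - p[rc7[0]]) * pstr(rc7[1:] + "A")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(bases[rng.choice(4, size=length, p=probs)]) if length else ""


def simulate_utr_sequences(config: SimulationConfig, calls: pd.DataFrame):
    """Tandem-UTR core/extension sequences with planted seed sites.

    ``calls`` must have columns ``event_id`` and ``significant`` (bool) for
    TandemUTR events; significant events form the ``shortened_significant``
    class.  Background is i.i.d. sequence in one of two GC strata; extensions
    of significant UTRs additionally receive Poisson-many planted 7mer-m8
    sites per planted miRNA so the realized density is about
    ``planted_fold`` x the analytic background density.  Cores never receive
    planted sites (enrichment is confined to extensions).

    Returns ``(regions, truth)``.
    """
    config.validate()
    rng = _rng(config.seed, "utr")
    rows, truth_rows = [], []
    planted_dna = {m: _revcomp(_rna_to_dna(config.mirna_sequences[m])[1:8])
                   for m in config.planted_mirnas}
    for rec in calls.itertuples(index=False):
        sig = bool(rec.significant)
        sig_class = "shortened_significant" if sig else "unchanged"
        p_hi = config.p_high_gc_significant if sig else config.p_high_gc_unchanged
        gc = config.gc_strata[1] if rng.random() < p_hi else config.gc_strata[0]
        core = _random_seq(rng, config.utr_core_len, gc)
        ext = _random_seq(rng, config.utr_ext_len, gc)
        planted_counts = {}
        if sig and config.planted_fold > 1.0 and len(ext) >= 7:
            ext_list = list(ext)
            occupied: list[tuple[int, int]] = []
            for mid, site in planted_dna.items():
                d0 = expected_site_density(config.mirna_sequences[mid], gc)
                lam = (config.planted_fold - 1.0) * d0 * len(ext)
                n_extra = int(rng.poisson(lam))
                placed = 0
                for _ in range(50 * max(n_extra, 1)):
                    if placed >= n_extra:
                        break
                    pos = int(rng.integers(0, len(ext) - len(site) + 1))
                    if any(pos < e and pos + len(site) > s for s, e in occupied):
                        continue
                    ext_list[pos:pos + len(site)] = list(site)
                    occupied.append((pos, pos + len(site)))
                    placed += 1
                planted_counts[mid] = placed
            ext = "".join(ext_list)
        rows.append(dict(event_id=rec.event_id,
                         gene_id=getattr(rec, "gene_id", rec.event_id),
                         sig_class=sig_class, gc=gc,
                         chrom=rec.event_id, strand="+",
                         core_start=0, core_end=config.utr_core_len,
                         ext_start=config.utr_core_len,
                         ext_end=config.utr_core_len + config.utr_ext_len,
                         core_seq=core, ext_seq=ext))
        truth_rows.append(dict(event_id=rec.event_id, sig_class=sig_class, gc=gc,
                               **{f"planted_{m}": planted_counts.get(m, 0)
                                  for m in config.planted_mirnas}))
    regions = pd.DataFrame(rows)
    truth = SyntheticTruth(utrs=pd.DataFrame(truth_rows))
    return regions, truth


def default_mirna_set(config: SimulationConfig) -> pd.DataFrame:
    """miRNA table (id, sequence, per-condition expression, expressed flag)."""
    rows = [dict(mirna_id=mid, sequence=seq, expr_control=10.0, expr_infected=10.0)
            for mid, seq in config.mirna_sequences.items()]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression fold changes
# ---------------------------------------------------------------------------

def simulate_expression_changes(config: SimulationConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Per-individual log2 fold changes linked to true per-individual delta-PSI.

    Genes of shifted events are "linked": their log2FC is an affine function
    of the donor's true delta-PSI plus Gaussian noise whose scale is set so
    the realized Spearman correlation is about ``rho_dpsi_fc`` (via the
    bivariate-normal relation rho_pearson = 2 sin(pi rho_spearman / 6)).
    Unlinked genes get exchangeable Gaussian noise.

    Returns a DataFrame indexed by gene_id with one column per individual.
    """
    config.validate()
    if truth.events is None or truth.event_individual is None:
        raise ValueError("event truth required before simulating expression changes")
    rng = _rng(config.seed, "expression")
    rho_s = config.rho_dpsi_fc
    rho_p = 2.0 * math.sin(math.pi * rho_s / 6.0)
    a = config.fc_slope

    wide = truth.event_individual.pivot(index="event_id", columns="individual_id",
                                        values="delta_psi")
    meta = truth.events.set_index("event_id")
    rows, index = [], []
    for event_id, d in wide.iterrows():
        gene_id = meta.loc[event_id, "gene_id"]
        linked = bool(meta.loc[event_id, "is_shifted"]) and abs(rho_s) > 0
        d = d.to_numpy(float)
        sd_d = float(np.std(d, ddof=1))
        offset = float(rng.normal(0.0, 0.5))
        if linked and sd_d > 1e-12:
            sigma = abs(a) * sd_d * math.sqrt(max(1.0 / rho_p**2 - 1.0, 0.0))
            sign = 1.0 if rho_s >= 0 else -1.0
            fc = offset + sign * a * d + rng.normal(0.0, sigma, size=d.size)
        else:
            fc = offset + rng.normal(0.0, config.null_fc_sd, size=d.size)
        rows.append(fc)
        index.append(gene_id)
    expr = pd.DataFrame(rows, index=pd.Index(index, name="gene_id"), columns=wide.columns)
    link_truth = pd.DataFrame({
        "gene_id": index,
        "event_id": wide.index,
        "linked": [bool(meta.loc[e, "is_shifted"]) and abs(rho_s) > 0 for e in wide.index],
        "target_rho": rho_s,
    })
    truth.expression = link_truth.reset_index(drop=True)
    return expr


# ---------------------------------------------------------------------------
# 3'-end reads
# ---------------------------------------------------------------------------

def simulate_threeprime_reads(config: SimulationConfig, truth: SyntheticTruth):
    """3'-end read positions around the two polyA sites of each tandem UTR.

    Each event lives on its own contig (named by event_id) with the proximal
    polyA site at ``utr_core_len`` and the distal site at
    ``utr_core_len + utr_ext_len``.  A read ends at the distal site with
    probability PSI (long-isoform usage) and at the proximal site otherwise,
    jittered by Normal(0, jitter_sd).

    Returns ``(reads, sites)`` as BED-style DataFrames.
    """
    config.validate()
    if truth.event_individual is None or truth.events is None:
        raise ValueError("event truth required before simulating 3'-end reads")
    rng = _rng(config.seed, "threeprime")
    prox = config.utr_core_len
    dist = config.utr_core_len + config.utr_ext_len
    tandem = truth.events.query("category == 'TandemUTR'")["event_id"]
    ind_truth = truth.event_individual.set_index(["event_id", "individual_id"])

    individuals = sorted(truth.event_individual["individual_id"].unique())
    individuals = individuals[: config.n_individuals_threeprime]

    chrom_parts, pos_parts, name_parts, site_rows = [], [], [], []
    for event_id in tandem:
        site_rows.append(dict(event_id=event_id, chrom=event_id,
                              proximal=prox, distal=dist, strand="+"))
        for ind in individuals:
            rec = ind_truth.loc[(event_id, ind)]
            for cond, psi in (("ctl", rec["psi_ni"]), ("inf", rec["psi_inf"])):
                n_reads = int(rng.poisson(config.depth_threeprime))
                if n_reads == 0:
                    continue
                at_distal = rng.random(n_reads) < psi
                pos = np.where(at_distal, dist, prox) + np.rint(
                    rng.normal(0.0, config.jitter_sd, size=n_reads)).astype(int)
                chrom_parts.append(np.repeat(event_id, n_reads))
                pos_parts.append(np.clip(pos, 0, None))
                name_parts.append(np.repeat(f"{ind}_{cond}", n_reads))
    if pos_parts:
        starts = np.concatenate(pos_parts)
        reads = pd.DataFrame({
            "chrom": np.concatenate(chrom_parts),
            "start": starts,
            "end": starts + 1,
            "name": np.concatenate(name_parts),
            "score": 0,
            "strand": "+",
        })
    else:
        reads = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    sites = pd.DataFrame(site_rows)
    return reads, sites
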