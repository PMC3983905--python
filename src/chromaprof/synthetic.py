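"""Synthetic chromatin cohort generator and recovery estimators.

The generator encodes a compact model of metazoan promoter chromatin:

* a phased nucleosome array per gene — an NDR containing the TSS, a -1
  nucleosome, and a +1 nucleosome whose entry site (5' DNA edge) sits
  ~50 bp downstream of the TSS (dyad at entry + 73), followed by a
  regular array at a fixed repeat length with per-gene positional
  fuzziness;
* fragment libraries per ChIPed factor mixing short factor footprints
  with mononucleosome-sized fragments produced when the factor is
  formaldehyde-crosslinked to a neighbouring nucleosome (probability
  ``p_x``), plus a uniform background fraction;
* per-gene PolII activity drawn log-normally, driving both library
  composition and CATCH-IT turnover signal;
* two named conditions, ``wt`` and ``k510r`` (catalytically dead Chd1):
  the mutant reduces nucleosome occupancy, redistributes total PolII
  into the promoter (stalling at positions ~20 bp inside each
  promoter-proximal nucleosome entry), shifts Ser2phos PolII out of the
  distal gene body, abolishes PolII-coupled promoter turnover, and adds
  a constant turnover increment in the gene body.

All outputs are pure functions of (presets, config, seed).  Streams are
split per purpose so e.g. nucleosome positions are identical across
conditions and factor libraries generated from the same cohort seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.signal import find_peaks

from .fragment_ops import SignalTrack
from .genomic_io import FragmentSet, GeneModel
from .metaprofile import Profile, WindowSpec

__all__ = [
    "ArchitecturePreset",
    "FootprintSpec",
    "TurnoverParams",
    "ConditionPreset",
    "SimConfig",
    "Cohort",
    "NucleosomeMap",
    "load_presets",
    "default_architecture",
    "default_condition",
    "default_sim_config",
    "sample_gene_cohort",
    "place_nucleosomes",
    "simulate_library",
    "simulate_catchit",
    "estimate_plus1_entry",
    "estimate_peak_offset",
]

FACTORS = ("total_polii", "ser2_polii", "chd1_wt", "chd1_k510r", "nucleosome")

# stable stream ids so every generator output is reproducible per purpose
_STREAM_LAYOUT = 10
_STREAM_DYADS = 11
_STREAM_ACTIVITY = 12
_STREAM_QPROM = 13
_STREAM_LIBRARY = 20
_STREAM_CATCHIT = 30

_FACTOR_ID = {f: i for i, f in enumerate(FACTORS)}
_CONDITION_ID = {"wt": 0, "k510r": 1}
_PLACEMENT_ID = {"default": 0, "genome_average": 1, "per_nucleosome": 2}


# ---------------------------------------------------------------------------
# presets


@dataclass(frozen=True)
class ArchitecturePreset:
    """Ground-truth promoter chromatin architecture."""

    nucleosome_footprint: int = 147
    plus1_entry: int = 50
    repeat_length: int = 190
    fuzz_sd: float = 15.0
    minus1_dyad: int = -170
    ndr: tuple[int, int] = (-96, 50)
    occupancy_decay: float = 0.85
    minus1_occupancy: float = 0.8

    def __post_init__(self) -> None:
        if not self.ndr[0] <= 0 <= self.ndr[1]:
            raise ValueError("NDR must contain the TSS (offset 0)")

    @property
    def plus1_dyad(self) -> int:
        return self.plus1_entry + self.nucleosome_footprint // 2

    def entry_of(self, k: int) -> int:
        """Entry site (5' edge) of the +k nucleosome, k >= 1."""
        return self.plus1_entry + (k - 1) * self.repeat_length


@dataclass(frozen=True)
class FootprintSpec:
    """Protected-fragment length distribution for one factor."""

    factor: str
    dist: str  # 'normal' | 'uniform'
    mean: float | None
    sd: float | None
    min_len: int
    max_len: int

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "uniform":
            ln = rng.integers(self.min_len, self.max_len + 1, size=n)
        else:
            ln = np.rint(rng.normal(self.mean, self.sd, size=n))
        return np.clip(ln, self.min_len, self.max_len).astype(np.int64)


@dataclass(frozen=True)
class TurnoverParams:
    basal: float = 0.20
    slope: float = 0.50
    ceiling: float = 1.70
    body_basal: float = 0.10
    body_coupling: float = 0.15
    delta: float = 0.0
    noise_sd: float = 0.05
    gene_noise_sd: float = 0.04
    background_level: float = 0.05
    decay_scale: float = 400.0


@dataclass(frozen=True)
class ConditionPreset:
    """Condition-specific multipliers layered over the shared architecture."""

    name: str
    nuc_occ_promoter: float = 1.0
    nuc_occ_body: float = 1.0
    promoter_gain: float = 1.0
    promoter_share_cap: float = 0.98
    ser2_body_fraction: float = 0.85
    turnover: TurnoverParams = field(default_factory=TurnoverParams)

    def __post_init__(self) -> None:
        for name in ("nuc_occ_promoter", "nuc_occ_body", "promoter_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"condition {self.name}: {name} must be > 0")


@dataclass(frozen=True)
class SimConfig:
    """Cohort layout and library-level simulation parameters."""

    seed: int
    n_genes: int = 2000
    length_median: int = 6000
    length_sigma: float = 0.45
    length_min: int = 3000
    length_max: int = 25000
    gap_min: int = 10500
    gap_max: int = 12000
    n_chroms: int = 4
    flank: int = 6000
    n_fragments: int = 200_000
    p_x: float = 0.3
    background_fraction: float = 0.05
    activity_sigma: float = 1.0
    elongation_sigma: float = 1.0
    promoter_body_ratio: float = 0.4286


@dataclass
class Cohort:
    """Genes plus the per-gene latent variables the libraries share.

    ``activity`` is PolII promoter activity (log-normal, long-tailed).
    ``elongation`` is per-gene elongation efficiency (log-normal): it
    sets the odds of a total-PolII event landing in the gene body vs the
    promoter and scales Ser2phos output, so wild-type stalling indices
    span orders of magnitude as observed.  ``q_promoter`` is the derived
    wild-type promoter share, ``1 / (1 + c * elongation)``.
    """

    genes: list[GeneModel]
    activity: np.ndarray
    elongation: np.ndarray
    q_promoter: np.ndarray
    chrom_sizes: dict[str, int]
    config: SimConfig

    @property
    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def activity_of(self, gene_id: str) -> float:
        return float(self.activity[self.gene_ids.index(gene_id)])


@dataclass
class NucleosomeMap:
    """Realized per-gene dyads (oriented bp from TSS) with occupancies.

    ``dyads[g]`` is ordered [-1, +1, +2, ...]; positions are identical
    across conditions generated from the same cohort seed — only the
    occupancies carry the condition multipliers.
    """

    dyads: list[np.ndarray]
    occupancy: list[np.ndarray]
    condition: str

    def plus_dyad(self, gene_idx: int, k: int) -> float:
        """Realized oriented dyad of the +k nucleosome."""
        return float(self.dyads[gene_idx][k])


def _yaml_presets() -> dict:
    text = resources.files("chromaprof").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def load_presets() -> dict:
    """Load the versioned preset file shipped with the package.

    Returns a dict with keys ``architecture`` (ArchitecturePreset),
    ``footprints`` (factor -> FootprintSpec), ``placements`` (raw dict),
    ``conditions`` (name -> ConditionPreset) and ``simulation`` (raw
    dict of SimConfig defaults).
    """
    raw = _yaml_presets()
    arch = ArchitecturePreset(
        nucleosome_footprint=raw["architecture"]["nucleosome_footprint"],
        plus1_entry=raw["architecture"]["plus1_entry"],
        repeat_length=raw["architecture"]["repeat_length"],
        fuzz_sd=raw["architecture"]["fuzz_sd"],
        minus1_dyad=raw["architecture"]["minus1_dyad"],
        ndr=tuple(raw["architecture"]["ndr"]),
        occupancy_decay=raw["architecture"]["occupancy_decay"],
        minus1_occupancy=raw["architecture"]["minus1_occupancy"],
    )
    foot = {
        name: FootprintSpec(factor=name, **spec) for name, spec in raw["footprints"].items()
    }
    conditions = {}
    for name, c in raw["conditions"].items():
        conditions[name] = ConditionPreset(
            name=name,
            nuc_occ_promoter=c["nuc_occ_promoter"],
            nuc_occ_body=c["nuc_occ_body"],
            promoter_gain=c["promoter_gain"],
            promoter_share_cap=c["promoter_share_cap"],
            ser2_body_fraction=c["ser2_body_fraction"],
            turnover=TurnoverParams(**c["turnover"]),
        )
    return {
        "version": raw["version"],
        "architecture": arch,
        "footprints": foot,
        "placements": raw["placements"],
        "conditions": conditions,
        "simulation": raw["simulation"],
    }


_PRESETS = None


def _presets() -> dict:
    global _PRESETS
    if _PRESETS is None:
        _PRESETS = load_presets()
    return _PRESETS


def default_architecture() -> ArchitecturePreset:
    return _presets()["architecture"]


def default_condition(name: str) -> ConditionPreset:
    conditions = _presets()["conditions"]
    if name not in conditions:
        raise KeyError(f"unknown condition {name!r}; available: {sorted(conditions)}")
    return conditions[name]


def default_sim_config(seed: int, **overrides) -> SimConfig:
    sim = dict(_presets()["simulation"])
    sim.update(overrides)
    return SimConfig(seed=seed, **sim)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


# ---------------------------------------------------------------------------
# cohort


def sample_gene_cohort(config: SimConfig) -> Cohort:
    """Lay out non-overlapping genes on ``n_chroms`` chromosomes.

    Gene lengths are log-normal (clipped), strands random, intergenic
    gaps uniform in ``[gap_min, gap_max]`` so that +/-5 kb analysis
    flanks never touch a neighbouring gene.  Per-gene PolII activity is
    log-normal with sd ``activity_sigma`` (long-tailed, spanning the
    quintile range); elongation efficiency is an independent log-normal
    latent from which each gene's wild-type promoter share of total
    PolII follows, so stalling indices span orders of magnitude.
    """
    rng_layout = _rng(config.seed, _STREAM_LAYOUT)
    n = config.n_genes
    lengths = np.clip(
        np.rint(rng_layout.lognormal(math.log(config.length_median), config.length_sigma, n)),
        config.length_min,
        config.length_max,
    ).astype(np.int64)
    strands = rng_layout.choice(["+", "-"], size=n)
    gaps = rng_layout.integers(config.gap_min, config.gap_max + 1, size=n)

    genes: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    per_chrom = math.ceil(n / config.n_chroms) if n else 0
    width = len(str(max(n - 1, 1)))
    for c in range(config.n_chroms):
        cursor = config.flank
        lo, hi = c * per_chrom, min((c + 1) * per_chrom, n)
        chrom = f"chr{c + 1}"
        for i in range(lo, hi):
            start, end = cursor, cursor + int(lengths[i])
            gid = f"g{i:0{width}d}"
            if strands[i] == "+":
                genes.append(GeneModel(gid, chrom, "+", tss=start, tes=end - 1))
            else:
                genes.append(GeneModel(gid, chrom, "-", tss=end - 1, tes=start))
            cursor = end + int(gaps[i])
        chrom_sizes[chrom] = cursor + config.flank

    activity = _rng(config.seed, _STREAM_ACTIVITY).lognormal(0.0, config.activity_sigma, n)
    elongation = _rng(config.seed, _STREAM_QPROM).lognormal(0.0, config.elongation_sigma, n)
    q = 1.0 / (1.0 + config.promoter_body_ratio * elongation)
    return Cohort(genes, activity, elongation, q, chrom_sizes, config)


def place_nucleosomes(
    cohort: Cohort,
    arch: ArchitecturePreset | None = None,
    condition: ConditionPreset | str = "wt",
) -> NucleosomeMap:
    """Realize the per-gene nucleosome array.

    Each gene gets a -1 dyad and a genic array (+1 dyad at entry + 73,
    then one dyad per repeat length while the wrapped DNA fits inside
    the gene), each jittered by the architecture's fuzziness sd.  The
    jitter stream depends only on the cohort seed, so positions are
    identical across conditions; occupancies are scaled by the
    condition's promoter-proximal and gene-body multipliers.
    """
    arch = arch or default_architecture()
    if isinstance(condition, str):
        condition = default_condition(condition)
    rng = _rng(cohort.config.seed, _STREAM_DYADS)
    half = arch.nucleosome_footprint // 2
    # promoter-proximal = -1, +1 and +2 nucleosomes
    prox_limit = arch.plus1_dyad + 1.5 * arch.repeat_length
    dyads, occs = [], []
    for gene in cohort.genes:
        k_max = max(0, (gene.length - half - arch.plus1_dyad) // arch.repeat_length + 1)
        ideal = np.concatenate(
            ([arch.minus1_dyad], arch.plus1_dyad + arch.repeat_length * np.arange(k_max))
        ).astype(float)
        realized = ideal + rng.normal(0.0, arch.fuzz_sd, size=len(ideal))
        occ = np.concatenate(
            ([arch.minus1_occupancy], arch.occupancy_decay ** np.arange(k_max))
        )
        scale = np.where(ideal <= prox_limit, condition.nuc_occ_promoter, condition.nuc_occ_body)
        dyads.append(realized)
        occs.append(occ * scale)
    return NucleosomeMap(dyads, occs, condition.name)


# ---------------------------------------------------------------------------
# libraries


def _gene_weights(factor: str, cohort: Cohort) -> np.ndarray:
    lengths = np.array([g.length for g in cohort.genes], dtype=float)
    if factor == "nucleosome":
        w = lengths
    elif factor == "ser2_polii":
        # elongating-PolII output scales with activity, gene length and
        # per-gene elongation efficiency
        w = cohort.activity * lengths * cohort.elongation
    else:  # promoter-recruited factors
        w = cohort.activity
    return w / w.sum()


def simulate_library(
    factor: str,
    condition: ConditionPreset | str,
    cohort: Cohort,
    arch: ArchitecturePreset | None = None,
    config: SimConfig | None = None,
    placement: str = "default",
) -> FragmentSet:
    """Simulate one ChIP fragment library.

    Per binding event the library mixes, with probability ``1 - p_x``, a
    short factor-footprint fragment placed by the factor's placement
    rule, and with probability ``p_x`` a mononucleosome-sized fragment
    centered on the nearest realized dyad (the factor crosslinked to its
    neighbouring nucleosome).  A ``background_fraction`` of fragments is
    uniform over the genome.  Genes are chosen proportional to activity
    (promoter factors), activity x length (elongating Ser2phos), or
    length (nucleosome libraries).

    ``placement`` selects among placement presets where the condition
    has more than one: for ``chd1_k510r`` either ``"genome_average"``
    (the default) or ``"per_nucleosome"`` (the processive-gene preset).
    """
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    arch = arch or default_architecture()
    config = config or cohort.config
    if isinstance(condition, str):
        condition = default_condition(condition)
    pl = _presets()["placements"]
    foot = _presets()["footprints"]
    if factor == "chd1_k510r" and placement == "default":
        placement = "genome_average"
    if placement not in _PLACEMENT_ID:
        raise ValueError(f"unknown placement {placement!r}")

    nmap = place_nucleosomes(cohort, arch, condition)
    rng = _rng(
        config.seed,
        _STREAM_LIBRARY,
        _FACTOR_ID[factor],
        _CONDITION_ID[condition.name],
        _PLACEMENT_ID[placement],
    )
    n_total = config.n_fragments
    n_bg = int(rng.binomial(n_total, config.background_fraction))
    n_events = n_total - n_bg

    weights = _gene_weights(factor, cohort)
    counts = rng.multinomial(n_events, weights)
    half_nuc = arch.nucleosome_footprint // 2
    mono = pl["mono_length"]
    fspec = foot["chd1"] if factor.startswith("chd1") else foot[factor]

    chroms, starts, ends = [], [], []
    for gi, n_g in enumerate(counts):
        if n_g == 0:
            continue
        gene = cohort.genes[gi]
        L = gene.length
        dy = nmap.dyads[gi]

        if factor == "nucleosome":
            occ = nmap.occupancy[gi]
            p = occ / occ.sum()
            centers = dy[rng.choice(len(dy), size=n_g, p=p)]
            lengths = np.clip(
                np.rint(rng.normal(mono["mean"], mono["sd"], n_g)),
                mono["min_len"],
                mono["max_len"],
            ).astype(np.int64)
        else:
            centers = _placement_centers(
                factor, condition, placement, gene, gi, cohort, dy, half_nuc, pl, rng, n_g
            )
            # crosslinked events ride on the nearest realized nucleosome
            x = rng.random(n_g) < config.p_x
            if x.any():
                idx = np.abs(centers[x][:, None] - dy[None, :]).argmin(axis=1)
                centers = centers.copy()
                centers[x] = dy[idx]
            lengths = np.empty(n_g, dtype=np.int64)
            lengths[~x] = fspec.sample(rng, int((~x).sum()))
            lengths[x] = np.clip(
                np.rint(rng.normal(mono["mean"], mono["sd"], int(x.sum()))),
                mono["min_len"],
                mono["max_len"],
            ).astype(np.int64)

        centers = np.rint(centers).astype(np.int64)
        if gene.strand == "+":
            gcenter = gene.tss + centers
        else:
            gcenter = gene.tss - centers
        s = gcenter - lengths // 2
        e = s + lengths
        size = cohort.chrom_sizes[gene.chrom]
        s = np.clip(s, 0, size - 1)
        e = np.clip(e, s + 1, size)
        chroms.extend([gene.chrom] * int(n_g))
        starts.append(s)
        ends.append(e)

    # uniform background over the genome
    if n_bg:
        cnames = sorted(cohort.chrom_sizes)
        sizes = np.array([cohort.chrom_sizes[c] for c in cnames], dtype=float)
        ci = rng.choice(len(cnames), size=n_bg, p=sizes / sizes.sum())
        blen = rng.integers(30, 181, size=n_bg)
        bstart = (rng.random(n_bg) * (sizes[ci] - blen)).astype(np.int64)
        chroms.extend(np.array(cnames, dtype=object)[ci])
        starts.append(bstart)
        ends.append(bstart + blen)

    if not chroms:
        return FragmentSet.from_records([])
    return FragmentSet(
        np.array(chroms, dtype=object),
        np.concatenate(starts),
        np.concatenate(ends),
    )


def _placement_centers(
    factor: str,
    condition: ConditionPreset,
    placement: str,
    gene: GeneModel,
    gene_idx: int,
    cohort: Cohort,
    dyads: np.ndarray,
    half_nuc: int,
    pl: dict,
    rng: np.random.Generator,
    n: int,
) -> np.ndarray:
    """Oriented footprint centers for one gene under the factor's placement rule."""
    L = gene.length

    def entry(k: int) -> float:  # 5' edge of the +k nucleosome (realized)
        return dyads[min(k, len(dyads) - 1)] - half_nuc

    if factor == "total_polii":
        q = float(cohort.q_promoter[gene_idx])
        if condition.name != "wt":
            q = min(q * condition.promoter_gain, condition.promoter_share_cap)
        at_prom = rng.random(n) < q
        centers = np.empty(n, dtype=float)
        n_b = int((~at_prom).sum())
        centers[~at_prom] = rng.uniform(300, L, size=n_b)
        n_p = int(at_prom.sum())
        if condition.name == "wt":
            centers[at_prom] = rng.normal(0.0, pl["tss_sd"], size=n_p)
        else:
            comp = rng.choice(4, size=n_p, p=pl["stall_weights"])
            c = np.empty(n_p, dtype=float)
            c[comp == 0] = rng.normal(0.0, pl["tss_sd"], size=int((comp == 0).sum()))
            for k in (1, 2, 3):
                m = comp == k
                c[m] = entry(k) + pl["stall_inset"] + rng.normal(0, pl["stall_sd"], int(m.sum()))
            centers[at_prom] = c
        return centers

    if factor == "ser2_polii":
        body = rng.random(n) < condition.ser2_body_fraction
        lo, hi = pl["ser2_early_window"]
        centers = np.empty(n, dtype=float)
        centers[~body] = rng.uniform(lo, hi, size=int((~body).sum()))
        centers[body] = rng.uniform(hi, max(L, hi + 1), size=int(body.sum()))
        return centers

    if factor == "chd1_wt":
        span, tail = pl["chd1_wt_span"], pl["chd1_wt_tail"]
        in_body = rng.random(n) < pl["chd1_wt_body_fraction"]
        centers = np.empty(n, dtype=float)
        centers[~in_body] = rng.uniform(0, span, size=int((~in_body).sum()))
        centers[in_body] = span + rng.exponential(tail, size=int(in_body.sum()))
        return np.minimum(centers, L - 1)

    if factor == "chd1_k510r":
        if placement == "genome_average":
            return rng.normal(pl["chd1_ga_center"], pl["chd1_ga_sd"], size=n)
        comp = rng.choice((1, 2, 3), size=n, p=pl["chd1_pn_weights"])
        centers = np.empty(n, dtype=float)
        for k in (1, 2, 3):
            m = comp == k
            centers[m] = entry(k) + pl["chd1_pn_inset"] + rng.normal(0, pl["chd1_pn_sd"], int(m.sum()))
        return centers

    raise ValueError(f"no placement rule for factor {factor!r}")


# ---------------------------------------------------------------------------
# CATCH-IT


def simulate_catchit(
    cohort: Cohort,
    condition: ConditionPreset | str = "wt",
    config: SimConfig | None = None,
) -> SignalTrack:
    """Dense CATCH-IT turnover track for a cohort under one condition.

    Per gene the promoter-region level is ``basal + slope *
    min(activity, ceiling)`` and the gene-body level ``body_basal +
    body_coupling * (activity * elongation) + delta`` (the body couples
    to elongating-PolII density); the two are blended with a
    smooth Gaussian positional decay centred on the TSS.  Intergenic
    positions sit at a background level.  Per-position Gaussian noise
    and a per-gene offset are added on top.
    """
    if isinstance(condition, str):
        condition = default_condition(condition)
    config = config or cohort.config
    tp = condition.turnover
    rng = _rng(config.seed, _STREAM_CATCHIT, _CONDITION_ID[condition.name])

    data = {c: np.full(sz, tp.background_level, dtype=float) for c, sz in cohort.chrom_sizes.items()}
    upstream = 600  # promoter bump covers the -1 nucleosome
    for gi, gene in enumerate(cohort.genes):
        act = cohort.activity[gi]
        prom = tp.basal + tp.slope * min(act, tp.ceiling)
        body = tp.body_basal + tp.body_coupling * act * cohort.elongation[gi] + tp.delta
        offsets = np.arange(-upstream, gene.length)
        blend = np.exp(-((offsets / tp.decay_scale) ** 2))
        level = body + (prom - body) * blend + rng.normal(0.0, tp.gene_noise_sd)
        arr = data[gene.chrom]
        if gene.strand == "+":
            lo = gene.tss - upstream
            arr[lo : lo + len(level)] = level
        else:
            hi = gene.tss + upstream  # genomic position of oriented -upstream
            arr[hi - len(level) + 1 : hi + 1] = level[::-1]
    for c in sorted(data):
        data[c] += rng.normal(0.0, tp.noise_sd, size=len(data[c]))
    return SignalTrack(
        data=data,
        normalization="raw",
        provenance={"signal": "catchit", "condition": condition.name, "seed": config.seed},
    )


# ---------------------------------------------------------------------------
# recovery estimators


def _smooth(values: np.ndarray, window: int = 31) -> np.ndarray:
    """Centered moving average with edge renormalization."""
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def estimate_plus1_entry(
    mono_profile: Profile,
    smooth_window: int = 31,
    min_search: tuple[int, int] = (-150, 100),
    half_wrap: int = 73,
) -> float:
    """Recover the +1 nucleosome entry site from a mononucleosome
    span-coverage metaprofile.

    The profile is smoothed with a centered moving average, the NDR
    minimum nearest the TSS is located, and the first local maximum
    downstream of it is taken as the +1 dyad peak; the entry site is
    that peak minus 73 bp (half the wrapped DNA).  Assumes span
    (occupancy) reduction of 111-140 bp fragments.
    """
    v = _smooth(mono_profile.values, smooth_window)
    offs = np.asarray(mono_profile.offsets)
    in_ndr = (offs >= min_search[0]) & (offs < min_search[1])
    if not in_ndr.any():
        raise ValueError("profile does not span the NDR search window")
    min_pos = offs[in_ndr][np.argmin(v[in_ndr])]
    after = offs > min_pos
    # require a real nucleosomal peak, not a noise wiggle in the NDR floor
    peaks, _ = find_peaks(v[after], distance=50, prominence=0.05 * np.ptp(v))
    if len(peaks) == 0:
        raise ValueError("no local maximum downstream of the NDR minimum")
    peak_off = float(offs[after][peaks[0]])
    return peak_off - half_wrap


def estimate_peak_offset(
    short_profile: Profile,
    search_window: WindowSpec | tuple[int, int],
    smooth_window: int = 31,
) -> float:
    """Position of the maximum of a smoothed short-fragment metaprofile
    within a search window (ties resolved to the leftmost position)."""
    if isinstance(search_window, WindowSpec):
        lo, hi = search_window.start_offset, search_window.end_offset
    else:
        lo, hi = search_window
    v = _smooth(short_profile.values, smooth_window)
    offs = np.asarray(short_profile.offsets)
    mask = (offs >= lo) & (offs < hi)
    if not mask.any():
        raise ValueError("profile not defined on the search window")
    vw = v[mask]
    if np.ptp(vw) == 0:
        raise ValueError("flat profile in the search window: no peak")
    # a smoothing plateau resolves to its center; separated equal peaks
    # resolve to the leftmost one
    at_max = np.flatnonzero(np.isclose(vw, vw.max(), rtol=1e-9, atol=0.0))
    breaks = np.flatnonzero(np.diff(at_max) > 1)
    first_run = at_max if len(breaks) == 0 else at_max[: breaks[0] + 1]
    return float(offs[mask][first_run[len(first_run) // 2]])
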