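"""Synthetic campaign data with the statistical structure real screens show.

Three generators emulate the inputs of a rabbit B-cell antibody discovery
campaign:

* ``generate_repertoire`` — paired VH/VL amino-acid repertoires with known
  germline origin, Poisson somatic hypermutation and shared-CDR3 lineages;
* ``generate_panel`` — multi-channel plate screening measurements with a
  Johnson SU optical-density background and planted binders/inhibitors;
* ``generate_competition`` — pairwise cross-competition ELISA matrices with
  planted epitope groups and optional asymmetric binders.

Every generated record carries its ground-truth labels so downstream
annotation, clustering, gating and binning can be validated against truth.
All randomness flows through one ``numpy`` generator per call, seeded from
the config, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import (
    GermlineReference,
    HEAVY_J_MOTIF,
    KAPPA_J_MOTIF,
    _locate_cdr3,
)
from .binning import CompetitionMatrix

# Residue pools exclude cysteine plus the chain's J-motif residue so that the
# anchor motifs required by annotation occur exactly once per sequence.
_HEAVY_POOL = list("ADEGHIKLMNPQRSTVY" "F")
_KAPPA_POOL = list("ADEGHIKLMNPQRSTVY" "W")

_FR4 = {"heavy": "WGQGTLVTVSS", "kappa": "FGQGTKVEIK"}

#: Reference V-core length matching the default Kabat-style CDR intervals.
_REF_CORE = 89
_REF_CDRS = {
    "heavy": {"cdr1": (25, 35), "cdr2": (49, 65)},
    "kappa": {"cdr1": (23, 34), "cdr2": (49, 56)},
}

CDR3_LENGTH_SUPPORT = range(4, 20)


def default_cdr3_length_law(mean: float = 11.4, sd: float = 2.7) -> dict[int, float]:
    """Truncated discrete Gaussian over CDR3 lengths 4..19 (rabbit CDR-H3)."""
    lengths = np.array(CDR3_LENGTH_SUPPORT)
    weights = np.exp(-0.5 * ((lengths - mean) / sd) ** 2)
    weights /= weights.sum()
    return dict(zip(lengths.tolist(), weights.tolist()))


def _pool(chain: str) -> list[str]:
    return _HEAVY_POOL if chain == "heavy" else _KAPPA_POOL


def _random_cdr3(rng: np.random.Generator, length: int, chain: str) -> str:
    return "".join(rng.choice(_pool(chain), size=length))


def generate_germlines(
    n: int,
    length: int = 110,
    seed: int = 0,
    chain: str = "heavy",
) -> list[GermlineReference]:
    """Generate *n* distinct germline V references of the given chain.

    Each sequence carries the anchors annotation relies on: a conserved
    cysteine closing framework 3 and a J motif (``W-G-x-G`` heavy,
    ``F-G-x-G`` kappa) opening framework 4.  The Kabat-style CDR1/CDR2
    intervals are scaled to the sequence length and stored on the reference.
    """
    if n < 1:
        raise ValueError("need n >= 1 germlines")
    if length < 60:
        raise ValueError("germline length must be >= 60")
    if chain not in ("heavy", "kappa"):
        raise ValueError(f"unknown chain {chain!r}")

    rng = np.random.default_rng(seed)
    fr4 = _FR4[chain]
    cdr3_len = max(4, min(19, length - len(fr4) - _REF_CORE))
    core_len = length - len(fr4) - cdr3_len
    factor = core_len / _REF_CORE
    cdr1 = tuple(int(round(x * factor)) for x in _REF_CDRS[chain]["cdr1"])
    cdr2 = tuple(int(round(x * factor)) for x in _REF_CDRS[chain]["cdr2"])
    if not (0 < cdr1[0] < cdr1[1] < cdr2[0] < cdr2[1] < core_len - 1):
        raise ValueError(f"length {length} too short for CDR layout")

    prefix = "VH1a" if chain == "heavy" else "VK1-"
    refs: list[GermlineReference] = []
    seen: set[str] = set()
    for i in range(n):
        while True:
            core = rng.choice(_pool(chain), size=core_len)
            core[core_len - 1] = "C"  # conserved Cys preceding CDR3
            if core_len >= 3:
                core[core_len - 3 : core_len - 1] = ["Y", "Y"]
            fr1_cys = max(1, cdr1[0] - 4)
            core[fr1_cys] = "C"  # first conserved framework cysteine
            cdr3 = _random_cdr3(rng, cdr3_len, chain)
            seq = "".join(core) + cdr3 + fr4
            if seq not in seen:
                seen.add(seq)
                break
        refs.append(
            GermlineReference(
                id=f"{prefix}{i + 1}", chain=chain, sequence=seq, cdr1=cdr1, cdr2=cdr2
            )
        )
    return refs


def generate_germline_set(
    n_heavy: int = 2,
    n_light: int = 2,
    length: int = 110,
    seed: int = 0,
) -> list[GermlineReference]:
    """Convenience wrapper: heavy + kappa references in one list."""
    heavy = generate_germlines(n_heavy, length=length, seed=seed, chain="heavy")
    light = generate_germlines(n_light, length=length, seed=seed + 1, chain="kappa")
    return heavy + light


@dataclass
class RepertoireSimConfig:
    """Conditions for a simulated VH/VL repertoire.

    Defaults mirror a single real screening campaign: 227 recombinant
    antibodies from 3 animals over 4 bleeds, CDR-H3 lengths on 4..19 around
    11.4 residues, a mean of 13 V-region replacements per heavy chain, and
    about one quarter of clones falling into shared-clonotype lineages.
    """

    n_clones: int = 227
    n_animals: int = 3
    n_bleeds: int = 4
    shm_rate: float = 13.0
    shm_rate_light: float | None = None  # defaults to shm_rate
    cdr3_length_law: dict[int, float] = field(default_factory=default_cdr3_length_law)
    lineage_fraction: float = 0.25
    lineage_mutations: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lineage_fraction <= 1.0:
            raise ValueError("lineage_fraction must be in [0, 1]")
        if self.shm_rate < 0:
            raise ValueError("shm_rate must be >= 0")
        if self.lineage_mutations < 0:
            raise ValueError("lineage_mutations must be >= 0")
        total = sum(self.cdr3_length_law.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("cdr3_length_law must sum to 1")
        if any(l not in CDR3_LENGTH_SUPPORT for l in self.cdr3_length_law):
            raise ValueError("cdr3_length_law support must lie within 4..19")


def _sample_length(rng: np.random.Generator, law: dict[int, float]) -> int:
    lengths = list(law.keys())
    probs = np.array(list(law.values()))
    return int(rng.choice(lengths, p=probs / probs.sum()))


def _mutate_cdr3(
    rng: np.random.Generator, cdr3: str, n_mut: int, chain: str
) -> str:
    if n_mut == 0 or not cdr3:
        return cdr3
    seq = list(cdr3)
    positions = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    for p in positions:
        choices = [a for a in _pool(chain) if a != seq[p]]
        seq[p] = rng.choice(choices)
    return "".join(seq)


def _build_chain(
    rng: np.random.Generator,
    germ: GermlineReference,
    cdr3: str,
    shm_rate: float,
) -> tuple[str, int]:
    """Clone chain = germline with its CDR3 swapped out plus Poisson SHM.

    Replacements land uniformly on V-core positions outside the CDR3 and
    never touch the conserved anchor cysteine or the J region, so annotation
    stays well-posed.  Returns (sequence, true replacement count).
    """
    motif = HEAVY_J_MOTIF if germ.chain == "heavy" else KAPPA_J_MOTIF
    cys, j_start = _locate_cdr3(germ.sequence, motif)
    seq = list(germ.sequence[: cys + 1]) + list(cdr3) + list(germ.sequence[j_start:])
    mutable = list(range(cys))  # V core excluding the anchor Cys
    n_mut = min(int(rng.poisson(shm_rate)), len(mutable))
    positions = rng.choice(mutable, size=n_mut, replace=False) if n_mut else []
    for p in positions:
        choices = [a for a in _pool(germ.chain) if a != seq[p]]
        seq[p] = rng.choice(choices)
    return "".join(seq), n_mut


def generate_repertoire(
    config: RepertoireSimConfig,
    germlines: list[GermlineReference],
) -> pd.DataFrame:
    """Simulate a paired VH/VL repertoire with ground-truth labels.

    Clones are organised into true clonotypes: a configurable fraction sits
    in multi-member lineages (members share germline and animal, differ by at
    most ``lineage_mutations`` replacements per CDR3 chain from the lineage
    founder, and may span bleeds); the rest are singletons.
    """
    heavy = [g for g in germlines if g.chain == "heavy"]
    light = [g for g in germlines if g.chain == "kappa"]
    if not heavy or not light:
        raise ValueError("need at least one heavy and one kappa germline")

    rng = np.random.default_rng(config.seed)
    shm_l = config.shm_rate if config.shm_rate_light is None else config.shm_rate_light

    n_lineage = int(round(config.lineage_fraction * config.n_clones))
    if n_lineage < 2:
        n_lineage = 0
    sizes: list[int] = []
    remaining = n_lineage
    while remaining >= 2:
        size = int(min(remaining, rng.integers(2, 6)))
        if remaining - size == 1:
            size += 1
        sizes.append(size)
        remaining -= size

    animals = [str(68 + i) for i in range(config.n_animals)]
    bleeds = list(range(1, config.n_bleeds + 1))

    rows: list[dict] = []
    clone_no = 0

    def emit(clonotype_id: str, animal: str, hg, lg, cdr3_h: str, cdr3_l: str) -> None:
        nonlocal clone_no
        clone_no += 1
        vh, r_h = _build_chain(rng, hg, cdr3_h, config.shm_rate)
        vl, r_l = _build_chain(rng, lg, cdr3_l, shm_l)
        rows.append(
            {
                "clone_id": f"clone{clone_no:04d}",
                "animal": animal,
                "bleed": int(rng.choice(bleeds)),
                "sort_arm": str(rng.choice(["panned", "preincubation"], p=[0.75, 0.25])),
                "vh": vh,
                "vl": vl,
                "true_vh_germline": hg.id,
                "true_vl_germline": lg.id,
                "true_clonotype": clonotype_id,
                "true_cdr3_h": cdr3_h,
                "true_cdr3_l": cdr3_l,
                "true_vh_replacements": r_h,
                "true_vl_replacements": r_l,
            }
        )

    for li, size in enumerate(sizes):
        animal = str(rng.choice(animals))
        hg = heavy[int(rng.integers(len(heavy)))]
        lg = light[int(rng.integers(len(light)))]
        founder_h = _random_cdr3(rng, _sample_length(rng, config.cdr3_length_law), "heavy")
        founder_l = _random_cdr3(rng, _sample_length(rng, config.cdr3_length_law), "kappa")
        for m in range(size):
            if m == 0:
                cdr3_h, cdr3_l = founder_h, founder_l
            else:
                cdr3_h = _mutate_cdr3(
                    rng, founder_h, int(rng.integers(0, config.lineage_mutations + 1)), "heavy"
                )
                cdr3_l = _mutate_cdr3(
                    rng, founder_l, int(rng.integers(0, config.lineage_mutations + 1)), "kappa"
                )
            emit(f"L{li + 1:03d}", animal, hg, lg, cdr3_h, cdr3_l)

    n_singletons = config.n_clones - sum(sizes)
    for si in range(n_singletons):
        animal = str(rng.choice(animals))
        hg = heavy[int(rng.integers(len(heavy)))]
        lg = light[int(rng.integers(len(light)))]
        cdr3_h = _random_cdr3(rng, _sample_length(rng, config.cdr3_length_law), "heavy")
        cdr3_l = _random_cdr3(rng, _sample_length(rng, config.cdr3_length_law), "kappa")
        emit(f"S{si + 1:04d}", animal, hg, lg, cdr3_h, cdr3_l)

    return pd.DataFrame(rows)


@dataclass
class PanelSimConfig:
    """Conditions for a simulated primary-screening plate panel.

    The optical-density background follows a Johnson SU law whose default
    99% quantile (~0.12 OD) sits in the range of real calibrated plate
    cut-offs; IgG concentrations are log-normal around ~0.25 ug/ml.
    """

    n_wells: int = 2000
    background_law: tuple[float, float, float, float] = (-1.5, 1.8, 0.04, 0.02)
    positive_fraction: float = 0.03
    positive_shift: tuple[float, float] = (1.0, 0.4)  # OD offset mean, sd
    igg_law: tuple[float, float] = (np.log(0.25), 1.1)  # log-space mean, sd
    igg_positive_fraction: float = 0.128
    inhibitor_fraction: float = 0.16
    fc_binder_fraction: float = 0.14
    cyno_cross_fraction: float = 0.9
    murine_cross_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "positive_fraction",
            "igg_positive_fraction",
            "inhibitor_fraction",
            "fc_binder_fraction",
            "cyno_cross_fraction",
            "murine_cross_fraction",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        gamma, delta, xi, lam = self.background_law
        if delta <= 0 or lam <= 0:
            raise ValueError("Johnson SU delta and lambda must be > 0")


def johnson_su_sample(
    rng: np.random.Generator,
    params: tuple[float, float, float, float],
    size: int,
) -> np.ndarray:
    """Draw from Johnson SU: X = xi + lam * sinh((Z - gamma) / delta)."""
    gamma, delta, xi, lam = params
    z = rng.standard_normal(size)
    return xi + lam * np.sinh((z - gamma) / delta)


def johnson_su_quantile(
    q: float, params: tuple[float, float, float, float]
) -> float:
    """Closed-form Johnson SU quantile."""
    gamma, delta, xi, lam = params
    z = stats.norm.ppf(q)
    return float(xi + lam * np.sinh((z - gamma) / delta))


def generate_panel(config: PanelSimConfig) -> pd.DataFrame:
    """Simulate a wide-format well table with all screening channels.

    Non-secreting wells draw IgG from the far low tail; IgG-positive wells
    draw from the log-normal law.  Antigen binders add a positive OD shift
    on top of the Johnson SU background; cross-reactivity and inhibition are
    planted on subsets of the binders.  ODs are clipped at zero.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_wells

    igg_pos = rng.random(n) < config.igg_positive_fraction
    igg = np.where(
        igg_pos,
        rng.lognormal(config.igg_law[0], config.igg_law[1], size=n),
        rng.uniform(0.0, 0.005, size=n),
    )

    binder = igg_pos & (rng.random(n) < (config.positive_fraction / max(config.igg_positive_fraction, 1e-12)))
    if config.positive_fraction == 0.0:
        binder = np.zeros(n, dtype=bool)
    cyno = binder & (rng.random(n) < config.cyno_cross_fraction)
    murine = binder & (rng.random(n) < config.murine_cross_fraction)
    fc_binder = igg_pos & (rng.random(n) < config.fc_binder_fraction)
    inhibitor = binder & (rng.random(n) < config.inhibitor_fraction)

    def od_channel(mask: np.ndarray) -> np.ndarray:
        background = johnson_su_sample(rng, config.background_law, n)
        shift = np.clip(
            rng.normal(config.positive_shift[0], config.positive_shift[1], size=n), 0, None
        )
        return np.clip(background + np.where(mask, shift, 0.0), 0.0, None)

    od_hu = od_channel(binder)
    od_cyno = od_channel(cyno)
    od_mu = od_channel(murine)
    od_fc = od_channel(fc_binder)

    inhib_biochem = np.where(
        inhibitor, rng.normal(80.0, 12.0, size=n), rng.normal(5.0, 12.0, size=n)
    )
    # cellular assay tracks the biochemical one tightly only at high inhibition
    cellular_noise_sd = np.clip((100.0 - inhib_biochem) * 0.35, 3.0, None)
    inhib_cell = inhib_biochem + rng.normal(0.0, 1.0, size=n) * cellular_noise_sd

    animals = rng.choice([str(68 + i) for i in range(3)], size=n)
    bleeds = rng.integers(1, 5, size=n)

    return pd.DataFrame(
        {
            "well_id": [f"well{i + 1:05d}" for i in range(n)],
            "animal": animals,
            "bleed": bleeds,
            "sort_arm": rng.choice(["panned", "preincubation"], size=n, p=[0.75, 0.25]),
            "igg_conc": igg,
            "od_hu": od_hu,
            "od_cyno": od_cyno,
            "od_mu": od_mu,
            "od_huFc": od_fc,
            "pct_inhibition_biochem": inhib_biochem,
            "pct_inhibition_cellular": inhib_cell,
            "true_igg_positive": igg_pos,
            "true_binder": binder,
            "true_cyno_cross": cyno,
            "true_murine_cross": murine,
            "true_fc_binder": fc_binder,
            "true_inhibitor": inhibitor,
        }
    )


@dataclass
class CompetitionSimConfig:
    """Conditions for a simulated cross-competition ELISA matrix.

    In a competition ELISA low OD means competition (shared epitope) and
    high OD means independent binding, so ``within_signal`` is the low-OD
    mean for same-group pairs and ``between_signal`` the high-OD mean for
    different-group pairs.
    """

    n_antibodies: int = 16
    n_groups: int = 6
    within_signal: float = 0.1
    between_signal: float = 1.0
    asymmetric_pairs: list[tuple[int, int]] = field(default_factory=list)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups > self.n_antibodies:
            raise ValueError("n_groups cannot exceed n_antibodies")
        if self.n_groups < 1:
            raise ValueError("need at least one group")
        for i, j in self.asymmetric_pairs:
            if not (0 <= i < self.n_antibodies and 0 <= j < self.n_antibodies):
                raise ValueError(f"asymmetric pair ({i}, {j}) out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_competition(
    config: CompetitionSimConfig,
) -> tuple[CompetitionMatrix, np.ndarray]:
    """Simulate a first-antibody x second-antibody competition matrix.

    Group sizes partition the antibodies as evenly as possible.  Entries for
    same-group ordered pairs (and the diagonal) draw around the low
    within-signal, different-group pairs around the high between-signal.
    Each listed asymmetric pair is flipped in that one direction only.
    Returns the matrix plus the ground-truth group label per antibody.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_antibodies, config.n_groups
    base, extra = divmod(n, k)
    labels = np.concatenate(
        [np.full(base + (1 if g < extra else 0), g) for g in range(k)]
    )

    same = labels[:, None] == labels[None, :]
    means = np.where(same, config.within_signal, config.between_signal).astype(float)
    for i, j in config.asymmetric_pairs:
        means[i, j] = config.between_signal if same[i, j] else config.within_signal
    values = np.clip(means + rng.normal(0.0, config.noise_sd, size=(n, n)), 0.0, None)

    ids = [f"mab{i + 1:03d}" for i in range(n)]
    return CompetitionMatrix(antibody_ids=ids, values=values), labels
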