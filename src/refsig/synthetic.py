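"""Synthetic paired-cohort generator with planted discriminative ASVs.

Emulates the statistical structure of denoised 16S count tables from a
two-group (case/control) study: compositional, overdispersed counts with
a small set of informative ASVs whose relative abundance separates the
groups, some of which are structurally absent from one group entirely.

The generative law is Dirichlet-multinomial. A baseline relative-abundance
profile is drawn log-normally (few dominant taxa, a long rare tail) and
scaled to a total Dirichlet concentration ``overdispersion`` — smaller
values give noisier compositions. Informative ASVs multiply their
concentration by ``exp(+effect_size/2)`` in one group and
``exp(-effect_size/2)`` in the other, so the expected case/control
relative-abundance ratio is approximately ``exp(effect_size)``. Library
sizes are shifted-Poisson. A configurable fraction of informative ASVs is
made structurally absent (zero concentration, hence zero counts in every
sample) in its depleted group.

A paired "validation cohort" can be generated whose ASVs are longer reads:
for each retained informative discovery ASV, one to three validation ASVs
are built to contain the discovery sequence verbatim, giving downstream
subsequence matching a known ground truth (the containment map).

Draw order is fixed and documented per operation (counts before
sequences), so a fixed seed reproduces every output bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import AsvTable

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_discovery",
    "generate_validation",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the two-group Dirichlet-multinomial simulation.

    Defaults describe a desk-scale study: 100 cases and 100 controls over
    500 ASVs, 15 of them informative at a log-fold effect of 2.0 on the
    relative-abundance scale, 20k-read libraries, a total Dirichlet
    concentration of 50 (strong 16S-like overdispersion), 150 nt discovery
    reads versus 250 nt validation reads, and one fifth of the informative
    ASVs structurally absent in their depleted group.
    """

    n_case: int = 100
    n_control: int = 100
    n_asv: int = 500
    n_informative: int = 15
    effect_size: float = 2.0
    library_size_mean: int = 20_000
    overdispersion: float = 50.0
    discovery_read_len: int = 150
    validation_read_len: int = 250
    frac_absent_in_one_group: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must be >= 1")
        if self.n_informative > self.n_asv:
            raise ValueError("n_informative cannot exceed n_asv")
        if self.discovery_read_len < 50 or self.validation_read_len < 50:
            raise ValueError("read lengths must be >= 50")
        if self.validation_read_len < self.discovery_read_len:
            raise ValueError("validation_read_len must be >= discovery_read_len")
        if not 0.0 <= self.frac_absent_in_one_group <= 1.0:
            raise ValueError("frac_absent_in_one_group must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.overdispersion <= 0 or self.library_size_mean <= 0:
            raise ValueError("overdispersion and library_size_mean must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    ``effects`` maps informative ASV ids to their log-fold effect (positive
    = enriched in cases). ``containment_map`` maps discovery ASV ids to the
    validation ASV ids engineered to contain their sequence verbatim; it is
    empty for discovery cohorts.
    """

    informative_asv_ids: list[str]
    effects: dict[str, float]
    containment_map: dict[str, list[str]] = field(default_factory=dict)


def _random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """i.i.d. uniform DNA, pairwise distinct (collisions redrawn)."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    # element-wise Gamma draws: exact zeros for alpha == 0 (structural absence)
    draws = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-12)), 0.0)
    total = draws.sum()
    if total == 0:  # pathological config; keep the draw valid
        draws = np.ones_like(alpha)
        total = draws.sum()
    return draws / total


def _sample_counts(
    rng: np.random.Generator,
    alpha_case: np.ndarray,
    alpha_control: np.ndarray,
    n_case: int,
    n_control: int,
    library_size_mean: int,
) -> np.ndarray:
    """Counts for cases then controls; per sample: library, composition, counts."""
    rows = []
    for group_alpha, n in ((alpha_case, n_case), (alpha_control, n_control)):
        for _ in range(n):
            library = 1 + rng.poisson(library_size_mean - 1)
            p = _dirichlet(rng, group_alpha)
            rows.append(rng.multinomial(library, p))
    return np.asarray(rows, dtype=np.int64)


def _build_alphas(
    rng: np.random.Generator, cfg: SyntheticConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Baseline profile, informative choice, effects, and group alphas.

    Draw order: baseline log-normal profile, informative indices, effect
    signs. The structural-absence assignment is deterministic (rarest
    informative taxa), so it consumes no randomness.
    """
    base = rng.lognormal(mean=0.0, sigma=1.5, size=cfg.n_asv)
    base = base / base.sum() * cfg.overdispersion
    # plant effects on non-rare taxa only (above-median baseline abundance):
    # a taxon observed in almost no sample cannot carry a log-fold effect,
    # so rare-tail "informative" features would make the ground truth vacuous
    eligible = np.flatnonzero(base >= np.median(base))
    if len(eligible) < cfg.n_informative:
        eligible = np.arange(cfg.n_asv)
    informative = np.sort(rng.choice(eligible, size=cfg.n_informative, replace=False))
    signs = rng.choice([-1.0, 1.0], size=cfg.n_informative)
    effects = signs * cfg.effect_size

    alpha_case = base.copy()
    alpha_control = base.copy()
    alpha_case[informative] *= np.exp(effects / 2.0)
    alpha_control[informative] *= np.exp(-effects / 2.0)

    n_absent = int(round(cfg.frac_absent_in_one_group * cfg.n_informative))
    if n_absent:
        # structural absence is given to the rarest informative taxa: a taxon
        # never observed in one whole group is plausible only when it is rare,
        # otherwise it would be a perfect single-feature biomarker
        chosen = np.argsort(base[informative], kind="stable")[:n_absent]
        for j in chosen:
            # absent from the depleted group, so absence reinforces the effect
            if effects[j] >= 0:
                alpha_control[informative[j]] = 0.0
            else:
                alpha_case[informative[j]] = 0.0
    return base, informative, effects, alpha_case, alpha_control


def generate_discovery(cfg: SyntheticConfig) -> tuple[AsvTable, SyntheticTruth]:
    """Generate a discovery cohort and its ground truth.

    Sample ids are ``case_000..`` then ``ctrl_000..``; ASV ids are
    ``asv_0000..`` in column order. Counts are drawn before sequences.
    """
    rng = np.random.default_rng(cfg.seed)
    _, informative, effects, alpha_case, alpha_control = _build_alphas(rng, cfg)
    counts = _sample_counts(
        rng, alpha_case, alpha_control, cfg.n_case, cfg.n_control, cfg.library_size_mean
    )
    sequences = _random_sequences(rng, cfg.n_asv, cfg.discovery_read_len)

    asv_ids = [f"asv_{j:04d}" for j in range(cfg.n_asv)]
    sample_ids = [f"case_{i:03d}" for i in range(cfg.n_case)] + [
        f"ctrl_{i:03d}" for i in range(cfg.n_control)
    ]
    labels = {s: ("case" if s.startswith("case") else "control") for s in sample_ids}
    table = AsvTable(
        sample_ids=sample_ids,
        asv_ids=asv_ids,
        counts=counts,
        sequences=dict(zip(asv_ids, sequences)),
        labels=labels,
    )
    truth = SyntheticTruth(
        informative_asv_ids=[asv_ids[j] for j in informative],
        effects={asv_ids[j]: float(e) for j, e in zip(informative, effects)},
    )
    return table, truth


def generate_validation(
    cfg: SyntheticConfig,
    discovery_truth: SyntheticTruth,
    discovery: AsvTable,
    drop_fraction: float = 0.0,
) -> tuple[AsvTable, SyntheticTruth]:
    """Generate an independent validation cohort with engineered containment.

    A fresh cohort is drawn under the same law (new baseline profile, new
    samples) over longer reads. For each discovery informative ASV that is
    not dropped, 1-3 validation ASVs are constructed whose sequences embed
    the discovery sequence verbatim at a random offset; the discovery ASV's
    signal (its group effect, including structural absence) is carried by
    those containing ASVs, with its concentration mass split among them.
    A ``drop_fraction`` of the informative ASVs get no containing ASV at
    all, emulating signature members absent from a second cohort.

    The RNG is seeded with ``cfg.seed + 1`` (one stream per operation).
    Draw order: background profile, drop choice, per-ASV containment
    layout, counts, background sequences, flank sequences.
    """
    if not 0.0 <= drop_fraction <= 1.0:
        raise ValueError("drop_fraction must be in [0, 1]")
    if cfg.validation_read_len < cfg.discovery_read_len:
        raise ValueError("validation_read_len must be >= discovery_read_len")
    rng = np.random.default_rng(cfg.seed + 1)

    informative = list(discovery_truth.informative_asv_ids)
    n_inform = len(informative)
    n_drop = int(round(drop_fraction * n_inform))
    dropped = set()
    if n_drop:
        dropped = {informative[j] for j in rng.choice(n_inform, size=n_drop, replace=False)}
    retained = [a for a in informative if a not in dropped]

    # background ASVs: same law, no planted effect
    base = rng.lognormal(mean=0.0, sigma=1.5, size=cfg.n_asv)
    base = base / base.sum() * cfg.overdispersion

    # containing ASVs for retained informative discovery ASVs
    containment: dict[str, list[str]] = {}
    extra_case: list[float] = []
    extra_control: list[float] = []
    extra_ids: list[str] = []
    embed_targets: list[str] = []  # discovery id each extra ASV embeds
    mass_scale = cfg.overdispersion / cfg.n_asv  # typical per-ASV concentration
    for disc_id in retained:
        effect = discovery_truth.effects[disc_id]
        k = int(rng.integers(1, 4))
        split = _dirichlet(rng, np.full(k, 5.0))
        mass = mass_scale * float(rng.lognormal(0.0, 1.0))
        ids = [f"val_{disc_id}_{i}" for i in range(k)]
        containment[disc_id] = ids
        for i in range(k):
            a_case = mass * split[i] * np.exp(effect / 2.0)
            a_ctrl = mass * split[i] * np.exp(-effect / 2.0)
            if disc_id in discovery_truth.effects and _is_absent(discovery, disc_id):
                # mirror structural absence of the discovery ASV
                if effect >= 0:
                    a_ctrl = 0.0
                else:
                    a_case = 0.0
            extra_case.append(a_case)
            extra_control.append(a_ctrl)
            extra_ids.append(ids[i])
            embed_targets.append(disc_id)

    alpha_case = np.concatenate([base, extra_case]) if extra_ids else base.copy()
    alpha_control = np.concatenate([base, extra_control]) if extra_ids else base.copy()
    counts = _sample_counts(
        rng, alpha_case, alpha_control, cfg.n_case, cfg.n_control, cfg.library_size_mean
    )

    background_ids = [f"vbg_{j:04d}" for j in range(cfg.n_asv)]
    background_seqs = _random_sequences(rng, cfg.n_asv, cfg.validation_read_len)
    sequences = dict(zip(background_ids, background_seqs))
    for asv_id, disc_id in zip(extra_ids, embed_targets):
        core = discovery.sequences[disc_id]
        flank_len = cfg.validation_read_len - len(core)
        offset = int(rng.integers(0, flank_len + 1))
        left = "".join(_BASES[rng.integers(0, 4, size=offset)])
        right = "".join(_BASES[rng.integers(0, 4, size=flank_len - offset)])
        sequences[asv_id] = left + core + right

    asv_ids = background_ids + extra_ids
    sample_ids = [f"vcase_{i:03d}" for i in range(cfg.n_case)] + [
        f"vctrl_{i:03d}" for i in range(cfg.n_control)
    ]
    labels = {s: ("case" if s.startswith("vcase") else "control") for s in sample_ids}
    table = AsvTable(
        sample_ids=sample_ids,
        asv_ids=asv_ids,
        counts=counts,
        sequences=sequences,
        labels=labels,
    )
    truth = SyntheticTruth(
        informative_asv_ids=extra_ids,
        effects={
            asv_id: discovery_truth.effects[disc_id]
            for asv_id, disc_id in zip(extra_ids, embed_targets)
        },
        containment_map=containment,
    )
    return table, truth


def _is_absent(table: AsvTable, asv_id: str) -> bool:
    """True if the ASV has zero counts in every sample of at least one group."""
    j = table.asv_ids.index(asv_id)
    col = table.counts[:, j]
    case_mask = np.array([table.labels[s] == "case" for s in table.sample_ids])
    return bool((col[case_mask] == 0).all() or (col[~case_mask] == 0).all())
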