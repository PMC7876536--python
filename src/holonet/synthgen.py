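"""Synthetic matched host/microbe count datasets with known structure.

The generator plants co-abundance modules (features loading on a shared
latent sample factor), cross-kingdom couplings (host and microbe module
factors sharing a common component), and trait-driven large effects (a
group-level trait such as the fresh-/salt-water indicator shifting module
factors), then emits realistic count tables: Poisson counts with log-normal
library sizes for the host transcriptome, zero-inflated negative-binomial
counts for the microbiota.  The ground truth (labels, factors, realized
couplings) is returned alongside so every pipeline stage is testable
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import AnnotationMap, OmicsMatrix, SampleTable


@dataclass(frozen=True)
class LargeEffect:
    """A trait-driven shift of module latent factors.

    ``size`` is in latent standard-deviation units: the standardized trait
    vector times ``size`` is added to each affected module's factor before
    renormalization to unit variance.
    """

    trait: str  # "WaterSW" or "Day"
    kingdom: str  # "host" | "microbe"
    modules: tuple  # 1-based module indices within the kingdom
    size: float


@dataclass(frozen=True)
class SynthConfig:
    seed: int
    feeds: tuple = ("FO", "VO", "FOVO", "VOFO")
    waters: tuple = ("FW", "SW")
    days: tuple = (0, 1, 2, 5, 9, 16, 20)
    replicates: int = 1
    # host transcriptome
    n_genes: int = 300
    host_module_sizes: tuple = (40, 30, 20, 15, 10)
    host_within_r: float = 0.8
    host_base_log2_range: tuple = (3.0, 8.0)
    host_depth: float = 3e5
    host_depth_sigma: float = 0.25  # sdlog of the log-normal library sizes
    # microbiota
    n_otus: int = 60
    microbe_module_sizes: tuple = (15, 10, 8)
    microbe_within_r: float = 0.8
    microbe_base_log2_range: tuple = (5.0, 10.0)
    microbe_depth: float = 5e4
    microbe_depth_sigma: float = 0.3
    zero_inflation: float = 0.15
    nb_dispersion: float = 0.1
    # structure
    couplings: tuple = ()  # (host module, microbe module, r)
    large_effects: tuple = ()  # LargeEffect instances

    def __post_init__(self) -> None:
        if sum(self.host_module_sizes) > self.n_genes:
            raise ValueError("host module sizes exceed n_genes")
        if sum(self.microbe_module_sizes) > self.n_otus:
            raise ValueError("microbe module sizes exceed n_otus")
        for _, _, r in self.couplings:
            if not -1.0 < r < 1.0:
                raise ValueError(f"infeasible coupling r = {r}")

    @property
    def n_samples(self) -> int:
        return len(self.feeds) * len(self.waters) * len(self.days) * self.replicates


@dataclass
class SynthTruth:
    host_labels: pd.Series  # gene -> module label (0 = background)
    microbe_labels: pd.Series
    host_factors: pd.DataFrame  # module x sample latent factors
    microbe_factors: pd.DataFrame
    realized_couplings: list  # dicts with host_module, microbe_module, target_r, realized_r
    samples: SampleTable


def _sample_table(config: SynthConfig, rng: np.random.Generator) -> SampleTable:
    rows = []
    for feed in config.feeds:
        for water in config.waters:
            base_w = 50.0 if water == "FW" else 200.0
            for day in config.days:
                for rep in range(1, config.replicates + 1):
                    sid = f"G_{water}_D{day}_{feed}_{rep}"
                    weight = base_w * (1.0 + 0.01 * day) * float(np.exp(rng.normal(0.0, 0.1)))
                    cf = float(np.clip(rng.normal(1.2, 0.1), 0.8, 1.6))
                    length = (1e4 * weight / cf) ** (1.0 / 3.0)
                    rows.append(
                        {
                            "sample_id": sid,
                            "day": day,
                            "water": water,
                            "feed": feed,
                            "sex": str(rng.choice(["M", "F"])),
                            "weight_g": weight,
                            "length_mm": length,
                        }
                    )
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleTable(df)


def _trait_vector(name: str, samples: SampleTable) -> np.ndarray:
    df = samples.table
    if name == "WaterSW":
        v = (df["water"] == "SW").to_numpy(dtype=float)
    elif name == "Day":
        v = df["day"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown large-effect trait {name!r}")
    sd = v.std()
    if sd == 0:
        raise ValueError(f"trait {name} is constant under this design")
    return (v - v.mean()) / sd


def _module_factors(
    n_modules: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    return rng.standard_normal((n_modules, n_samples))


def generate(config: SynthConfig):
    """Generate (host counts, microbe counts, sample table, truth).

    Deterministic given the config (which carries the mandatory seed).
    """
    rng = np.random.default_rng(config.seed)
    samples = _sample_table(config, rng)
    sample_ids = samples.sample_ids
    n = len(sample_ids)

    n_hmod = len(config.host_module_sizes)
    n_mmod = len(config.microbe_module_sizes)
    f_host = _module_factors(n_hmod, n, rng)
    f_microbe = _module_factors(n_mmod, n, rng)

    # cross-kingdom couplings: replace both factors with a shared-component mix
    realized = []
    for hm, mm, r in config.couplings:
        z = rng.standard_normal(n)
        a = np.sqrt(abs(r))
        b = np.sqrt(1.0 - abs(r))
        f_host[hm - 1] = a * z + b * rng.standard_normal(n)
        f_microbe[mm - 1] = np.sign(r) * a * z + b * rng.standard_normal(n)
        realized.append({"host_module": hm, "microbe_module": mm, "target_r": r})

    # trait-driven large effects, then renormalize affected factors
    for eff in config.large_effects:
        t = _trait_vector(eff.trait, samples)
        target = f_host if eff.kingdom == "host" else f_microbe
        for m in eff.modules:
            target[m - 1] = (target[m - 1] + eff.size * t) / np.sqrt(1.0 + eff.size**2)

    for rec in realized:
        rec["realized_r"] = float(
            np.corrcoef(f_host[rec["host_module"] - 1], f_microbe[rec["microbe_module"] - 1])[0, 1]
        )

    def build_kingdom(n_feat, sizes, within_r, factors, base_range, prefix, modules_abundant):
        labels = np.zeros(n_feat, dtype=int)
        x = rng.standard_normal((n_feat, n))  # background = pure noise
        loading = np.sqrt(within_r)
        pos = 0
        for m, size in enumerate(sizes, start=1):
            idx = slice(pos, pos + size)
            labels[pos : pos + size] = m
            noise = rng.standard_normal((size, n))
            x[idx] = loading * factors[m - 1] + np.sqrt(1.0 - within_r) * noise
            pos += size
        base = rng.uniform(base_range[0], base_range[1], size=n_feat)
        if modules_abundant:
            # planted module members sit in the upper half of the abundance
            # range: co-abundance structure is only observable for taxa
            # abundant enough to escape dropout and counting noise
            n_mod = sum(sizes)
            mid = 0.5 * (base_range[0] + base_range[1])
            base[:n_mod] = rng.uniform(mid, base_range[1], size=n_mod)
        abundance = 2.0 ** (base[:, None] + x)
        ids = [f"{prefix}{i + 1:04d}" for i in range(n_feat)]
        return labels, x, abundance, ids

    h_labels, _, h_abund, gene_ids = build_kingdom(
        config.n_genes, config.host_module_sizes, config.host_within_r,
        f_host, config.host_base_log2_range, "gene_", modules_abundant=False,
    )
    m_labels, _, m_abund, otu_ids = build_kingdom(
        config.n_otus, config.microbe_module_sizes, config.microbe_within_r,
        f_microbe, config.microbe_base_log2_range, "OTU_", modules_abundant=True,
    )

    # host counts: transcript fractions sampled at a log-normal depth — the
    # per-sample renormalization mirrors RNA-seq compositionality
    h_rel = h_abund / h_abund.sum(axis=0, keepdims=True)
    h_depth = np.exp(rng.normal(np.log(config.host_depth), config.host_depth_sigma, size=n))
    host_counts = rng.poisson(h_rel * h_depth[None, :]).astype(float)

    # microbe counts: absolute abundances scaled to the target depth on
    # average (constant scale, so co-varying taxa are not cancelled by a
    # per-sample denominator), then negative binomial + dropout
    m_depth = np.exp(rng.normal(np.log(config.microbe_depth), config.microbe_depth_sigma, size=n))
    mu = m_abund * (m_depth[None, :] / m_abund.sum(axis=0).mean())
    phi = config.nb_dispersion
    if phi > 0:
        nb_n = 1.0 / phi
        nb_p = nb_n / (nb_n + mu)
        microbe_counts = rng.negative_binomial(nb_n, nb_p).astype(float)
    else:
        microbe_counts = rng.poisson(mu).astype(float)
    if config.zero_inflation > 0:
        # dropout is strongly abundance-dependent, as in real marker-gene
        # data: detection failures concentrate in the rarest taxa.  The
        # quadratic rank profile integrates to 1, so the marginal zero rate
        # stays at the configured level.
        order = np.argsort(np.argsort(mu.mean(axis=1)))  # 0 = rarest
        rank = order / max(config.n_otus - 1, 1)
        p_zero = np.clip(config.zero_inflation * 3.0 * (1.0 - rank) ** 2, 0.0, 0.95)
        microbe_counts[rng.random(microbe_counts.shape) < p_zero[:, None]] = 0.0

    host = OmicsMatrix(pd.DataFrame(host_counts, index=gene_ids, columns=sample_ids), "host")
    microbe = OmicsMatrix(pd.DataFrame(microbe_counts, index=otu_ids, columns=sample_ids), "microbe")
    truth = SynthTruth(
        host_labels=pd.Series(h_labels, index=gene_ids),
        microbe_labels=pd.Series(m_labels, index=otu_ids),
        host_factors=pd.DataFrame(
            f_host, index=[f"hM{i + 1}" for i in range(n_hmod)], columns=sample_ids
        ),
        microbe_factors=pd.DataFrame(
            f_microbe, index=[f"mM{i + 1}" for i in range(n_mmod)], columns=sample_ids
        ),
        realized_couplings=realized,
        samples=samples,
    )
    return host, microbe, samples, truth


# ---------------------------------------------------------------------------
# named study configurations
#
# These are the fixed conditions under which the pipeline's statistical
# behavior is characterized (planted-module recovery, null calibration,
# coupling power, large-effect correction).  The integration studies use
# clean count noise (no dropout, Poisson counts) so the planted coupling is
# realized at its nominal value at the eigennode level; the bundled fixture
# keeps realistic noise.


def module_recovery_config(seed: int) -> SynthConfig:
    """Five planted host modules (sizes 10-40, within-module r ~ 0.8) in a
    200-gene, 56-sample design; used to measure module recovery."""
    return SynthConfig(
        seed=seed,
        days=(0, 1, 2, 5, 9, 16, 20),
        replicates=1,
        n_genes=200,
        host_module_sizes=(40, 30, 20, 15, 10),
        host_within_r=0.8,
    )


def null_calibration_config(seed: int) -> SynthConfig:
    """Fully decoupled host/microbe data over 14 sample groups (2 waters x
    7 days, 2 replicates); no couplings, no trait effects."""
    return SynthConfig(
        seed=seed,
        feeds=("FO",),
        waters=("FW", "SW"),
        days=(1, 2, 5, 9, 16, 20, 30),
        replicates=2,
        n_genes=60,
        host_module_sizes=(12, 10, 8),
        n_otus=40,
        microbe_module_sizes=(8, 6),
        zero_inflation=0.02,
        nb_dispersion=0.05,
    )


def coupling_power_config(seed: int, n_couplings: int = 1) -> SynthConfig:
    """Planted cross-kingdom couplings at r = 0.8 over 14 sample groups
    (4 replicates each); clean count noise so the eigennode-level coupling
    realizes the nominal value."""
    if n_couplings == 1:
        microbe_sizes = (12, 10)
        couplings = ((1, 1, 0.8),)
    else:
        microbe_sizes = (12, 10, 8)
        couplings = tuple((k, k, 0.8) for k in range(1, n_couplings + 1))
    return SynthConfig(
        seed=seed,
        feeds=("FO",),
        waters=("FW", "SW"),
        days=(1, 2, 5, 9, 16, 20, 30),
        replicates=4,
        n_genes=400,
        host_module_sizes=(25, 20, 15),
        n_otus=120,
        microbe_module_sizes=microbe_sizes,
        couplings=couplings,
        zero_inflation=0.0,
        nb_dispersion=0.0,
    )


def large_effect_config(seed: int, with_microbe: bool = False) -> SynthConfig:
    """A strong water-type factor driving three host modules (and optionally
    one microbe module); the target of latent-effect estimation/removal."""
    effects = [LargeEffect("WaterSW", "host", (1, 2, 3), 1.5)]
    kwargs = {}
    if with_microbe:
        effects = [LargeEffect("WaterSW", "host", (1, 2), 1.5),
                   LargeEffect("WaterSW", "microbe", (1,), 1.5)]
        kwargs = dict(feeds=("FO", "VO"), replicates=2,
                      n_otus=60, microbe_module_sizes=(10, 8))
    return SynthConfig(
        seed=seed,
        feeds=kwargs.pop("feeds", ("FO",)),
        waters=("FW", "SW"),
        days=(1, 2, 5, 9, 16, 20, 30),
        replicates=kwargs.pop("replicates", 4),
        n_genes=150,
        host_module_sizes=(20, 15, 12),
        large_effects=tuple(effects),
        **kwargs,
    )


FIXTURE_SEED = 20240915


def fixture_config() -> SynthConfig:
    """Configuration of the small bundled fixture (300 genes, 60 OTUs,
    56 samples in a 4 feeds x 2 waters x 7 days design)."""
    return SynthConfig(
        seed=FIXTURE_SEED,
        couplings=((1, 1, 0.8), (2, 2, 0.75)),
        large_effects=(
            LargeEffect("WaterSW", "host", (1, 2), 2.0),
            LargeEffect("WaterSW", "microbe", (1,), 2.0),
        ),
    )


def fixture_small():
    """Deterministic small dataset used by the documentation and tests."""
    return generate(fixture_config())


def fixture_annotation(truth: SynthTruth, rng_seed: int = 7, n_noise_terms: int = 5) -> AnnotationMap:
    """Synthetic gene->term annotation aligned with the planted host modules:
    each planted module gets a dedicated term over its members plus random
    background genes, and a few fully random terms are added."""
    rng = np.random.default_rng(rng_seed)
    genes = list(truth.host_labels.index)
    gene_terms: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for m in sorted(set(truth.host_labels) - {0}):
        term = f"TERM:{m:04d}"
        desc[term] = f"planted process {m}"
        members = list(truth.host_labels.index[truth.host_labels == m])
        background = rng.choice(genes, size=max(2, len(members) // 4), replace=False)
        for g in list(members) + list(background):
            gene_terms.setdefault(g, set()).add(term)
    for t in range(n_noise_terms):
        term = f"TERM:R{t:03d}"
        desc[term] = f"random process {t}"
        for g in rng.choice(genes, size=12, replace=False):
            gene_terms.setdefault(g, set()).add(term)
    return AnnotationMap(gene_terms, desc)
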