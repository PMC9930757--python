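"""Synthetic generator for the rat skeletal-muscle contusion study design.

Emulates the shape of the qPCR dataset the screening framework was built
for: a control group plus 12 contusion time points (4-48 h in 4-h steps),
6 animals per group, a 28-gene candidate panel split into six
ARE-status x GO-category subgroups, and two stable reference genes
(RPL13, RPL32).  Per-animal measurements of this kind are not publicly
deposited, so everything downstream is exercised on this generator.

The noise model is lognormal on relative expression — equivalently
Gaussian on delta-Ct — which matches the multiplicative form of the
(1 + Eff.)^-ddCt quantification model and keeps expression strictly
positive.  For a lognormal with log-scale SD sigma, the coefficient of
variation on the natural scale is sqrt(exp(sigma^2) - 1), so the
per-subgroup ``subgroup_sigma`` values set the between-animal CV almost
directly (CV ~= sigma for small sigma).

Default between-animal sigmas are graded across subgroups (ARE-CC most
homogeneous, ARE+MF least).  The magnitudes are illustrative: the source
study reports no per-animal variance components, so the defaults were
chosen to span the CV range typical of tissue qPCR panels (10-35%) while
preserving the qualitative homogeneity ordering the framework is meant
to detect.

Each ARE+ gene's 3'UTR carries a planted Class I or Class II motif
cassette scoring > 3 under the local ARE score; ARE- and reference UTRs
are rejection-sampled to contain no AUUUA pentamer at all.  Class III
(diffuse AU-richness without a pentamer) is never planted because it has
no constructive motif definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .are_screen import ARE_NEG, ARE_POS, GeneRecord, SUBGROUPS, are_score, classify_are

#: Candidate panel of the screening study: subgroup -> (symbol, accession).
CANDIDATE_PANEL: dict[str, list[tuple[str, str]]] = {
    "ARE-CC": [
        ("Rae1", "NM_001033708"), ("Myg1", "NM_001005545"),
        ("Rabepk", "NM_001024871"), ("Tmem100", "NM_001017479"),
        ("Lin37", "NM_001106245"), ("Lrrc41", "NM_001009710"),
    ],
    "ARE-BP": [
        ("Prrx2", "NM_001105739"), ("Abhd2", "NM_001106275"),
        ("Prr5", "NM_001012121"), ("Fbxw4", "NM_001107600"),
        ("Rhbdd3", "NM_001013875"),
    ],
    "ARE-MF": [
        ("Ipo4", "NM_001106038"), ("Prr3", "NM_212544"),
        ("Arid5a", "NM_001034934"), ("Trit1", "NM_001108676"),
        ("Rcc1l", "NM_001108332"),
    ],
    "ARE+CC": [
        ("Sc65", "NM_021581"), ("Tmem45b", "NM_001033067"),
        ("Leprot", "NM_020099"), ("Fam210a", "NM_001007688"),
    ],
    "ARE+BP": [
        ("Impact", "NM_001012235"), ("Asb5", "NM_001044247"),
        ("Hs6st1", "NM_001108210"), ("Ier3", "NM_212505"),
    ],
    "ARE+MF": [
        ("Samd4b", "NM_001107498"), ("Dclre1b", "NM_001025687"),
        ("Dennd5a", "NM_001107546"), ("Slfn3", "NM_053687"),
    ],
}

REFERENCE_GENES = [("RPL13", "NM_031101"), ("RPL32", "NM_013226")]

CONTROL_LABEL = "control"

LN2 = math.log(2.0)

#: Class I cassette: two isolated pentamers in a U-rich (U/G) frame, 9 nt
#: apart so they earn the clustering bonus; score 4.0, no Class II core.
_CLASS_I_CASSETTE = "UUGUUGUUG" + "AUUUA" + "UUGUUGUUG" + "AUUUA" + "UUGUUGUUG"
#: Class II cassette: two chained UUAUUUA(U/A)(U/A) cores in a poly-U frame.
_CLASS_II_CASSETTE = "U" * 15 + "UUAUUUAUUUUAUUUAUU" + "U" * 15

_MAX_REJECTION_ATTEMPTS = 1000


def default_group_labels(n_groups: int = 13) -> list[str]:
    """Control plus contusion times at 4-h steps: 4h, 8h, ..., 48h."""
    return [CONTROL_LABEL] + [f"{4 * (i + 1)}h" for i in range(n_groups - 1)]


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic dataset."""

    n_groups: int = 13
    n_per_group: int = 6
    genes_per_subgroup: dict[str, int] = field(
        default_factory=lambda: {
            "ARE-CC": 6, "ARE-BP": 5, "ARE-MF": 5,
            "ARE+CC": 4, "ARE+BP": 4, "ARE+MF": 4,
        }
    )
    #: between-animal lognormal shape (SD of log expression) per subgroup
    subgroup_sigma: dict[str, float] = field(
        default_factory=lambda: {
            "ARE-CC": 0.10, "ARE-MF": 0.15, "ARE-BP": 0.20,
            "ARE+CC": 0.25, "ARE+BP": 0.30, "ARE+MF": 0.35,
        }
    )
    efficiency_range: tuple[float, float] = (0.85, 1.05)
    #: max |log2 fold change| of the time profiles; scalar or per-subgroup
    profile_amplitude: Union[float, Mapping[str, float]] = 2.0
    seed: int = 0
    utr_length: int = 600
    n_replicates: int = 3
    technical_sd: float = 0.05  # replicate-to-replicate Ct noise (cycles)
    reference_sigma: float = 0.02  # between-animal sigma of reference genes
    base_ct_range: tuple[float, float] = (18.0, 30.0)

    def __post_init__(self) -> None:
        if self.n_groups < 2 or self.n_per_group < 1:
            raise ValueError("n_groups >= 2 and n_per_group >= 1 required")
        if any(c <= 0 for c in self.genes_per_subgroup.values()):
            raise ValueError("genes_per_subgroup counts must be positive")
        if set(self.genes_per_subgroup) - set(SUBGROUPS):
            raise ValueError("unknown subgroup label in genes_per_subgroup")
        if any(s < 0 for s in self.subgroup_sigma.values()):
            raise ValueError("subgroup_sigma values must be >= 0")
        lo, hi = self.efficiency_range
        if not (0.8 <= lo <= hi <= 1.1):
            raise ValueError("efficiency_range must lie within [0.8, 1.1]")
        if self.utr_length < 80:
            raise ValueError("utr_length too short to host a motif cassette")

    @property
    def group_labels(self) -> list[str]:
        return default_group_labels(self.n_groups)

    def amplitude_for(self, subgroup: str) -> float:
        if isinstance(self.profile_amplitude, Mapping):
            return float(self.profile_amplitude[subgroup])
        return float(self.profile_amplitude)


@dataclass
class GenePanel:
    """A generated candidate panel with its ground truth."""

    records: list[GeneRecord]
    utr_sequences: dict[str, str]
    true_profiles: dict[str, np.ndarray]  # per-group mean log expression
    true_sigma: dict[str, float]
    base_ct: dict[str, float]
    config: SimulationConfig

    @property
    def target_records(self) -> list[GeneRecord]:
        return [r for r in self.records if not r.is_reference]

    @property
    def reference_symbols(self) -> list[str]:
        return [r.symbol for r in self.records if r.is_reference]


def _symbols_for(subgroup: str, count: int) -> list[tuple[str, str]]:
    known = CANDIDATE_PANEL[subgroup]
    if count <= len(known):
        return known[:count]
    tag = subgroup.replace("ARE", "A").replace("+", "p").replace("-", "m")
    extra = [(f"Syn{tag}{i:02d}", "") for i in range(len(known) + 1, count + 1)]
    return known + extra


def _random_utr_without_pentamer(
    rng: np.random.Generator, length: int, symbol: str
) -> str:
    bases = np.array(list("ACGU"))
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        seq = "".join(rng.choice(bases, size=length))
        if "AUUUA" not in seq:
            return seq
    raise RuntimeError(
        f"could not sample a pentamer-free UTR for gene {symbol} "
        f"after {_MAX_REJECTION_ATTEMPTS} attempts"
    )


def _utr_with_cassette(
    rng: np.random.Generator, length: int, cassette: str, symbol: str
) -> str:
    pad = length - len(cassette)
    left = int(rng.integers(10, pad - 10))
    head = _random_utr_without_pentamer(rng, left, symbol)
    tail = _random_utr_without_pentamer(rng, pad - left, symbol)
    return head + cassette + tail


def _smooth_profile(
    rng: np.random.Generator, n_groups: int, amplitude_log2: float
) -> np.ndarray:
    """Sum of 1-2 low-frequency sine components, zero at the control point,
    scaled so the peak |log2 fold change| equals ``amplitude_log2``."""
    t = np.arange(n_groups, dtype=float)
    span = n_groups - 1
    f = np.zeros(n_groups)
    for _ in range(int(rng.integers(1, 3))):
        freq = rng.uniform(0.5, 2.0)
        f += rng.normal() * np.sin(np.pi * freq * t / span)
    peak = np.max(np.abs(f))
    if peak == 0.0:  # vanishing draw; fall back to one fixed component
        f = np.sin(np.pi * t / span)
        peak = 1.0
    return f * (amplitude_log2 * LN2 / peak)


def generate_gene_panel(config: SimulationConfig) -> GenePanel:
    """Build the candidate panel: records, 3'UTRs, profiles, ground truth.

    Deterministic for a given (config, seed).  ARE+ genes alternate planted
    Class I and Class II cassettes; ARE- and reference genes get
    pentamer-free UTRs.
    """
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.efficiency_range
    records: list[GeneRecord] = []
    utrs: dict[str, str] = {}
    profiles: dict[str, np.ndarray] = {}
    sigmas: dict[str, float] = {}
    base_ct: dict[str, float] = {}

    for subgroup in SUBGROUPS:
        count = config.genes_per_subgroup.get(subgroup, 0)
        is_pos = subgroup.startswith(ARE_POS)
        go = subgroup[-2:]
        amp = config.amplitude_for(subgroup)
        for j, (symbol, accession) in enumerate(_symbols_for(subgroup, count)):
            if is_pos:
                cassette = _CLASS_I_CASSETTE if j % 2 == 0 else _CLASS_II_CASSETTE
                seq = _utr_with_cassette(rng, config.utr_length, cassette, symbol)
            else:
                seq = _random_utr_without_pentamer(rng, config.utr_length, symbol)
            profile = _smooth_profile(rng, config.n_groups, amp)
            are_class, _ = classify_are(seq)
            score = are_score(seq)
            log2fc_signed = profile[np.argmax(np.abs(profile))] / LN2
            records.append(
                GeneRecord(
                    symbol=symbol,
                    accession=accession,
                    are_status=ARE_POS if is_pos else ARE_NEG,
                    are_class=are_class,
                    are_score=score,
                    in_ared=is_pos,
                    go_category=(go,),
                    subgroup=subgroup,
                    log2fc=float(log2fc_signed),
                    adj_p=float(rng.uniform(1e-6, 1e-3)),
                    efficiency=float(rng.uniform(lo, hi)),
                )
            )
            utrs[symbol] = seq
            profiles[symbol] = profile
            sigmas[symbol] = float(config.subgroup_sigma.get(subgroup, 0.0))
            base_ct[symbol] = float(rng.uniform(*config.base_ct_range))

    for symbol, accession in REFERENCE_GENES:
        seq = _random_utr_without_pentamer(rng, config.utr_length, symbol)
        records.append(
            GeneRecord(
                symbol=symbol,
                accession=accession,
                are_status=ARE_NEG,
                are_class="none",
                are_score=are_score(seq),
                in_ared=False,
                go_category=(),
                subgroup=None,
                log2fc=0.0,
                adj_p=1.0,
                efficiency=float(rng.uniform(lo, hi)),
                is_reference=True,
            )
        )
        utrs[symbol] = seq
        profiles[symbol] = np.zeros(config.n_groups)
        sigmas[symbol] = config.reference_sigma
        base_ct[symbol] = float(rng.uniform(*config.base_ct_range))

    return GenePanel(records, utrs, profiles, sigmas, base_ct, config)


def simulate_ct_table(panel: GenePanel, config: Optional[SimulationConfig] = None) -> pd.DataFrame:
    """Simulate per-well Ct values for the full design.

    For animal ``a`` in group ``t`` and gene ``g`` the true relative
    expression is ``R = exp(profile_g(t) + eps)`` with
    ``eps ~ N(0, sigma_g^2)``; the well-level cycle threshold is
    ``Ct = Ct0_g - ln(R) / ln(1 + E_g)`` plus Gaussian technical noise per
    replicate.  Columns: sample_id, animal_id, group, gene, replicate, ct.
    """
    cfg = config or panel.config
    rng = np.random.default_rng([cfg.seed, 1])
    groups = cfg.group_labels
    n_animals = cfg.n_per_group
    animal_ids = [f"{g}_a{i + 1}" for g in groups for i in range(n_animals)]
    group_of = np.repeat(groups, n_animals)
    n_rows_per_gene = len(animal_ids) * cfg.n_replicates

    frames = []
    for rec in panel.records:
        g = rec.symbol
        profile = panel.true_profiles[g]
        sigma = panel.true_sigma[g]
        eps = rng.normal(0.0, sigma, size=len(animal_ids))
        log_r = np.repeat(profile, n_animals) + eps
        ct_mean = panel.base_ct[g] - log_r / math.log1p(rec.efficiency)
        ct = (
            np.repeat(ct_mean, cfg.n_replicates)
            + rng.normal(0.0, cfg.technical_sd, size=n_rows_per_gene)
        )
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(animal_ids, cfg.n_replicates),
                    "animal_id": np.repeat(animal_ids, cfg.n_replicates),
                    "group": np.repeat(group_of, cfg.n_replicates),
                    "gene": g,
                    "replicate": np.tile(
                        np.arange(1, cfg.n_replicates + 1), len(animal_ids)
                    ),
                    "ct": ct,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_dilution_series(
    gene: GeneRecord,
    levels: int = 5,
    config: Optional[SimulationConfig] = None,
    noise_sd: float = 0.0,
    intercept: float = 20.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Five-fold serial dilution series (1, 1:5, 1:25, ...) for one gene.

    Ct at relative concentration ``d`` is
    ``intercept - ln(d) / ln(1 + E_g)``, optionally with Gaussian Ct noise.
    """
    if levels < 3:
        raise ValueError("at least 3 dilution levels are required")
    conc = 5.0 ** -np.arange(levels, dtype=float)
    ct = intercept - np.log(conc) / math.log1p(gene.efficiency)
    if noise_sd > 0.0:
        if rng is None:
            seed = config.seed if config is not None else 0
            rng = np.random.default_rng([seed, 2])
        ct = ct + rng.normal(0.0, noise_sd, size=levels)
    return pd.DataFrame(
        {"gene": gene.symbol, "relative_concentration": conc, "ct": ct}
    )


def simulate_sample_qc(
    panel: GenePanel, config: Optional[SimulationConfig] = None
) -> pd.DataFrame:
    """Per-sample RNA quality table (OD260/OD280 and RIN), all passing."""
    cfg = config or panel.config
    rng = np.random.default_rng([cfg.seed, 3])
    animal_ids = [
        f"{g}_a{i + 1}" for g in cfg.group_labels for i in range(cfg.n_per_group)
    ]
    return pd.DataFrame(
        {
            "sample_id": animal_ids,
            "od_ratio": rng.uniform(1.82, 2.0, size=len(animal_ids)),
            "rin": rng.uniform(7.5, 9.5, size=len(animal_ids)),
        }
    )
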