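"""Synthetic TMT phosphoproteomics experiments with planted ground truth.

The generator emulates a multi-region TMT experiment at the level of the
site-quantification table: three groups (caput, corpus, cauda by default)
with five replicate channels each, ~10^2-10^4 phosphosites over ~10^2-10^3
proteins, an S/T/Y residue mix matching sperm phosphoproteomes (89.1 / 10.24
/ 0.66 %), localization probabilities drawn from a mixture so the class-I
filter has work to do, and a configurable fraction of sites whose parent
protein is absent from the protein table (the calibration fallback path).

Abundances are multiplicative: channel value = base x group-effect x
2**N(0, noise_sd_log2), so a planted log2 effect is exact in the noiseless
group means. Differential sites put the full effect on the last group versus
the first, and half the effect on intermediate groups (the intermediate
phenotype of corpus sperm). Planted kinases imprint their motif consensus on
a share of the regulated sites' flanking windows, with decoy kinases for the
enrichment analysis to reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .io import CENTER, PAD, WINDOW_LENGTH, ProteinRecord, SiteRecord, StudyDesign
from .kinase import KinaseSpec

WILDCARD = "X"
_AA = pio.AMINO_ACIDS


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class PlantedKinase:
    """A kinase whose activity is planted into the regulated sites."""

    name: str
    consensus: str  # 15-mer, 'X' wildcards, fixed S/T/Y center
    direction: str  # "up" or "down"
    family: str = "Other"


#: canonical basophilic CaMK-type motif (hydrophobic -5, R -3, hydrophobic +1)
CAMK_CONSENSUS = "XXLXRXXSLXXXXXX"
#: canonical proline-directed CDK-type motif (P +1, K +3)
CMGC_CONSENSUS = "XXXXXXXSPXKXXXX"

_DEFAULT_PLANTED = (
    PlantedKinase("CAMK2A", CAMK_CONSENSUS, "up", "CAMK"),
    PlantedKinase("CDK1", CMGC_CONSENSUS, "down", "CMGC"),
)

_DECOY_FAMILIES = ("AGC", "CK1", "STE", "TKL", "Other")


@dataclass
class SimulationConfig:
    n_proteins: int = 200
    n_sites: int = 1000
    n_channels_per_group: int = 5
    groups: tuple[str, ...] = ("caput", "corpus", "cauda")
    residue_props: tuple[float, float, float] = (0.891, 0.1024, 0.0066)
    frac_diff_sites: float = 0.1
    effect_log2fc: float = 1.5
    frac_protein_unquantified: float = 0.1
    noise_sd_log2: float = 0.25
    planted_kinases: tuple[PlantedKinase, ...] = _DEFAULT_PLANTED
    seed: int = 0
    # secondary knobs
    frac_low_localization: float = 0.15
    motif_frac: float = 0.6
    n_decoy_kinases: int = 10
    n_reference_windows: int = 10
    couple_proteins: bool = False  # make protein abundance track the planted effect

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.n_sites <= 0 or self.n_channels_per_group <= 0:
            raise ConfigError("sizes must be positive")
        if abs(sum(self.residue_props) - 1.0) > 1e-9:
            raise ConfigError(
                f"residue_props must sum to 1, got {sum(self.residue_props)!r}"
            )
        for name in ("frac_diff_sites", "frac_protein_unquantified", "frac_low_localization"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} not in [0, 1]")
        if self.effect_log2fc < 0 or self.noise_sd_log2 < 0:
            raise ConfigError("effect_log2fc and noise_sd_log2 must be nonnegative")
        if len(self.groups) < 2:
            raise ConfigError("need at least two groups")
        for pk in self.planted_kinases:
            if pk.direction not in ("up", "down"):
                raise ConfigError(f"planted kinase direction {pk.direction!r}")


@dataclass
class GroundTruth:
    diff_site_ids_up: frozenset[str]
    diff_site_ids_down: frozenset[str]
    active_kinases: dict[str, str]
    unquantified_protein_ids: frozenset[str]
    motif_site_ids: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diff_site_ids_up & self.diff_site_ids_down:
            raise ConfigError("up and down planted site sets overlap")

    def to_dict(self) -> dict:
        return {
            "diff_site_ids_up": sorted(self.diff_site_ids_up),
            "diff_site_ids_down": sorted(self.diff_site_ids_down),
            "active_kinases": dict(self.active_kinases),
            "unquantified_protein_ids": sorted(self.unquantified_protein_ids),
            "motif_site_ids": {k: sorted(v) for k, v in self.motif_site_ids.items()},
        }


def _validate_consensus(consensus: str) -> None:
    if len(consensus) != WINDOW_LENGTH:
        raise ValueError(f"consensus must be length {WINDOW_LENGTH}, got {len(consensus)}")
    if consensus[CENTER] not in "STY":
        raise ValueError(f"consensus center {consensus[CENTER]!r} must be S/T/Y")
    bad = set(consensus) - set(_AA + WILDCARD + PAD)
    if bad:
        raise ValueError(f"consensus contains invalid characters {sorted(bad)}")


def generate_windows(consensus: str, n: int, seed: int | np.random.Generator) -> list[str]:
    """Draw n windows matching a motif consensus.

    Fixed positions are copied verbatim; ``X`` wildcard positions are drawn
    uniformly from the 20 amino acids. Deterministic under ``seed``.
    """
    _validate_consensus(consensus)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wild = [i for i, c in enumerate(consensus) if c == WILDCARD]
    out = []
    for _ in range(n):
        chars = list(consensus)
        draws = rng.integers(0, len(_AA), size=len(wild))
        for i, d in zip(wild, draws):
            chars[i] = _AA[d]
        out.append("".join(chars))
    return out


def _random_window(residue: str, position: int, rng: np.random.Generator) -> str:
    """A random flanking window with the given center, padded at the N-terminus
    for sites within 7 residues of the protein start."""
    chars = [_AA[i] for i in rng.integers(0, len(_AA), size=WINDOW_LENGTH)]
    chars[CENTER] = residue
    n_pad = max(0, CENTER + 1 - position)  # position is 1-based
    for i in range(n_pad):
        chars[i] = PAD
    return "".join(chars)


def default_design(config: SimulationConfig) -> StudyDesign:
    channels, group_of, replicate_of = [], {}, {}
    for g in config.groups:
        for r in range(1, config.n_channels_per_group + 1):
            ch = f"{g}_{r}"
            channels.append(ch)
            group_of[ch] = g
            replicate_of[ch] = r
    return StudyDesign(channels, group_of, replicate_of)


def generate_experiment(
    config: SimulationConfig,
) -> tuple[list[SiteRecord], list[ProteinRecord], StudyDesign, list[KinaseSpec], GroundTruth]:
    """Generate one complete synthetic experiment with ground truth."""
    rng = np.random.default_rng(config.seed)
    design = default_design(config)
    n_groups = len(config.groups)
    n_ch = len(design.channels)
    group_index = np.array(
        [config.groups.index(design.group_of[c]) for c in design.channels]
    )

    # --- parent proteins ---------------------------------------------------
    accessions = [f"SP{i:04d}" for i in range(config.n_proteins)]
    parent_idx = rng.integers(0, config.n_proteins, size=config.n_sites)
    n_unq = int(round(config.frac_protein_unquantified * config.n_sites))
    unq_sites = rng.choice(config.n_sites, size=n_unq, replace=False) if n_unq else np.array([], int)
    unq_accessions = {int(s): f"UNQ{j:04d}" for j, s in enumerate(sorted(unq_sites))}

    # --- residues, positions, ids ------------------------------------------
    residues = rng.choice(["S", "T", "Y"], size=config.n_sites, p=list(config.residue_props))
    positions = rng.integers(1, 801, size=config.n_sites)

    # --- planted differential sites ----------------------------------------
    n_diff = int(round(config.frac_diff_sites * config.n_sites))
    n_up = n_diff // 2
    diff_idx = rng.choice(config.n_sites, size=n_diff, replace=False)
    up_idx = set(int(i) for i in diff_idx[:n_up])
    down_idx = set(int(i) for i in diff_idx[n_up:])

    # --- planted kinase motif assignment -----------------------------------
    motif_of_site: dict[int, PlantedKinase] = {}
    for direction, idx_set in (("up", up_idx), ("down", down_idx)):
        planted = [pk for pk in config.planted_kinases if pk.direction == direction]
        if not planted or not idx_set:
            continue
        ordered = sorted(idx_set)
        n_motif = int(round(config.motif_frac * len(ordered)))
        chosen = rng.choice(len(ordered), size=n_motif, replace=False)
        for j, c in enumerate(sorted(chosen)):
            motif_of_site[ordered[int(c)]] = planted[j % len(planted)]

    # --- windows ------------------------------------------------------------
    windows = []
    for i in range(config.n_sites):
        pk = motif_of_site.get(i)
        if pk is not None:
            residues[i] = pk.consensus[CENTER]
            positions[i] = max(int(positions[i]), CENTER + 1)  # full window, no padding
            windows.append(generate_windows(pk.consensus, 1, rng)[0])
        else:
            windows.append(_random_window(str(residues[i]), int(positions[i]), rng))

    # unique site ids: bump positions on collision
    used: set[str] = set()
    site_accs = []
    for i in range(config.n_sites):
        acc = unq_accessions.get(i, accessions[int(parent_idx[i])])
        site_accs.append(acc)
        while f"{acc}_{residues[i]}{positions[i]}" in used:
            positions[i] += 1
        used.add(f"{acc}_{residues[i]}{positions[i]}")

    # --- localization probabilities -----------------------------------------
    loc = np.empty(config.n_sites)
    low = rng.random(config.n_sites) < config.frac_low_localization
    loc[low] = rng.uniform(0.2, 0.74, size=int(low.sum()))
    loc[~low] = rng.uniform(0.9, 1.0, size=int((~low).sum()))
    for i in up_idx | down_idx:  # planted sites always pass the class-I filter
        if loc[i] < 0.9:
            loc[i] = float(rng.uniform(0.9, 1.0))

    # --- intensities ---------------------------------------------------------
    # per-group multiplicative effect: full effect on the last group, linear
    # ramp over intermediate groups (half effect on the middle of three)
    ramp = group_index / (n_groups - 1)
    site_base = rng.lognormal(mean=np.log(1e6), sigma=1.0, size=config.n_sites)
    site_noise = 2.0 ** rng.normal(0.0, config.noise_sd_log2, size=(config.n_sites, n_ch))
    site_sign = np.zeros(config.n_sites)
    for i in up_idx:
        site_sign[i] = 1.0
    for i in down_idx:
        site_sign[i] = -1.0
    site_effect = 2.0 ** (site_sign[:, None] * config.effect_log2fc * ramp[None, :])
    site_vals = site_base[:, None] * site_effect * site_noise

    prot_base = rng.lognormal(mean=np.log(1e7), sigma=1.0, size=config.n_proteins)
    prot_noise = 2.0 ** rng.normal(0.0, config.noise_sd_log2, size=(config.n_proteins, n_ch))
    prot_effect = np.ones((config.n_proteins, n_ch))
    if config.couple_proteins:
        # proteins inherit their (first) planted site's effect, so the
        # protein-level calibration should cancel it downstream
        for i in sorted(up_idx | down_idx):
            if i in unq_accessions:
                continue
            p = int(parent_idx[i])
            prot_effect[p] = 2.0 ** (site_sign[i] * config.effect_log2fc * ramp)
    prot_vals = prot_base[:, None] * prot_effect * prot_noise

    # --- assemble records -----------------------------------------------------
    sites = [
        SiteRecord(
            protein_accession=site_accs[i],
            position=int(positions[i]),
            residue=str(residues[i]),
            localization_probability=float(loc[i]),
            window=windows[i],
            intensities={ch: float(site_vals[i, j]) for j, ch in enumerate(design.channels)},
        )
        for i in range(config.n_sites)
    ]
    proteins = [
        ProteinRecord(
            accessions[p],
            {ch: float(prot_vals[p, j]) for j, ch in enumerate(design.channels)},
        )
        for p in range(config.n_proteins)
    ]

    # --- kinase reference ------------------------------------------------------
    kinases: list[KinaseSpec] = []
    for pk in config.planted_kinases:
        kinases.append(
            KinaseSpec(
                name=pk.name,
                family=pk.family,
                reference_windows=generate_windows(
                    pk.consensus, config.n_reference_windows, rng
                ),
            )
        )
    for j in range(config.n_decoy_kinases):
        chars = [WILDCARD] * WINDOW_LENGTH
        chars[CENTER] = "S" if rng.random() < 0.9 else "T"
        fixed_pos = rng.choice(
            [i for i in range(WINDOW_LENGTH) if i != CENTER], size=3, replace=False
        )
        for fp in fixed_pos:
            chars[int(fp)] = _AA[int(rng.integers(0, len(_AA)))]
        kinases.append(
            KinaseSpec(
                name=f"DECOY{j:02d}",
                family=_DECOY_FAMILIES[j % len(_DECOY_FAMILIES)],
                reference_windows=generate_windows(
                    "".join(chars), config.n_reference_windows, rng
                ),
            )
        )

    motif_sites: dict[str, set[str]] = {}
    for i, pk in motif_of_site.items():
        motif_sites.setdefault(pk.name, set()).add(sites[i].site_id)
    truth = GroundTruth(
        diff_site_ids_up=frozenset(sites[i].site_id for i in up_idx),
        diff_site_ids_down=frozenset(sites[i].site_id for i in down_idx),
        active_kinases={pk.name: pk.direction for pk in config.planted_kinases},
        unquantified_protein_ids=frozenset(unq_accessions.values()),
        motif_site_ids={k: frozenset(v) for k, v in motif_sites.items()},
    )
    return sites, proteins, design, kinases, truth


def write_experiment(outdir, config: SimulationConfig) -> dict[str, str]:
    """Generate an experiment and write its five artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites, proteins, design, kinases, truth = generate_experiment(config)
    paths = {
        "sites": str(outdir / "sites.tsv"),
        "proteins": str(outdir / "proteins.tsv"),
        "design": str(outdir / "design.tsv"),
        "kinases": str(outdir / "kinases.tsv"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
    pio.write_site_table(sites, paths["sites"], design)
    pio.write_protein_table(proteins, paths["proteins"], design)
    pio.write_design(design, paths["design"])
    pio.write_kinase_reference(kinases, paths["kinases"])
    pio.write_json(truth.to_dict(), paths["ground_truth"])
    return paths
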