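"""Ground-truthed simulation of blue-native PAGE AP-MS fraction tables.

The generator emulates a 48-fraction separation in which the bait migrates as
two partially overlapping high-mass peaks ("entities"). Each non-contaminant
protein's expected intensity in fraction ``f`` is

    sum_e  ratio[p, e] * amount_e * exp(-(f - apex_e - shift)^2 / (2 width_e^2))

evaluated at integer fractions, truncated (not renormalized) at the gel
bounds; ``shift`` is a whole-fraction offset applied to the second replicate
to emulate gel-cutting differences. Noise is multiplicative log-normal with a
configurable coefficient of variation, cells drop out (are reported as 0)
independently with a configurable rate, and iBAQ columns are the intensity
columns divided by a seed-deterministic per-protein theoretical-peptide
count. Contaminant rows get unstructured random intensities and carry the
contaminant flag.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import yaml

from .io_tables import QuantTable, write_quant_table, write_marker_ladder

__all__ = [
    "EntitySpec",
    "SubunitSpec",
    "SyntheticTruth",
    "default_truth",
    "expected_intensity",
    "simulate_table",
    "write_fixture",
    "truth_to_yaml",
    "truth_from_yaml",
]

_PEPCOUNT_STREAM = 7001  # rng stream tags; arbitrary but fixed
_NOISE_STREAM = 7002
_CONTAM_STREAM = 7003


@dataclass(frozen=True)
class EntitySpec:
    """One bait-defined assembly: a Gaussian peak in fraction space."""

    label: str
    apex_fraction: int
    width: float
    bait_amount: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("entity width must be > 0")
        if self.bait_amount < 0:
            raise ValueError("bait_amount must be nonnegative")


@dataclass(frozen=True)
class SubunitSpec:
    """A simulated protein and its abundance relative to the bait per entity.

    ``per_entity_ratio`` holds one nonnegative scalar per entity, in entity
    order. Contaminants have all ratios zero and draw unstructured profiles.
    """

    protein_id: str
    gene_name: str
    per_entity_ratio: tuple[float, ...]
    is_bait: bool = False
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_entity_ratio", tuple(float(r) for r in self.per_entity_ratio))
        if any(r < 0 for r in self.per_entity_ratio):
            raise ValueError("per_entity_ratio values must be nonnegative")
        if self.is_contaminant and any(r > 0 for r in self.per_entity_ratio):
            raise ValueError("contaminants must have all per_entity_ratio = 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Full ground truth for one simulated experiment (both replicates)."""

    n_fractions: int
    entities: tuple[EntitySpec, ...]
    subunits: tuple[SubunitSpec, ...]
    noise_cv: float = 0.1
    dropout_rate: float = 0.1
    replicate_shift: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "entities", tuple(self.entities))
        object.__setattr__(self, "subunits", tuple(self.subunits))
        if self.n_fractions < 2:
            raise ValueError("n_fractions must be >= 2")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for ent in self.entities:
            if not 1 <= ent.apex_fraction <= self.n_fractions:
                raise ValueError(f"entity {ent.label}: apex outside [1, {self.n_fractions}]")
        baits = [s for s in self.subunits if s.is_bait]
        if len(baits) != 1:
            raise ValueError(f"exactly one bait required, found {len(baits)}")
        for sub in self.subunits:
            if not sub.is_contaminant and len(sub.per_entity_ratio) != len(self.entities):
                raise ValueError(f"{sub.protein_id}: ratio count != entity count")

    @property
    def bait(self) -> SubunitSpec:
        return next(s for s in self.subunits if s.is_bait)

    def complex_member_ids(self) -> list[str]:
        """Proteins present in every entity (the simulated complex proper)."""
        return [
            s.protein_id
            for s in self.subunits
            if not s.is_contaminant and all(r > 0 for r in s.per_entity_ratio)
        ]

    def entity_member_ids(self, entity_index: int) -> list[str]:
        """Proteins with nonzero abundance in entity *entity_index* (0-based)."""
        return [
            s.protein_id
            for s in self.subunits
            if not s.is_contaminant and s.per_entity_ratio[entity_index] > 0
        ]


def default_truth(
    seed: int = 0,
    noise_cv: float = 0.1,
    dropout_rate: float = 0.1,
    replicate_shift: int = 2,
) -> SyntheticTruth:
    """Default two-assembly ground truth.

    48 fractions; two entities with apexes 28 and 34 (both inside the default
    regression window [26, 36]) of width 1 fraction, the higher-mass entity
    1.5x more abundant; a bait; seven flat-ratio core subunits; three 2x
    high-mass-enriched subunits; one both-entity partner, two entity-II-only
    partners, one entity-I-only partner; six contaminants.

    Apex separation and amplitude asymmetry are tuned so that, at the default
    analysis settings, the noiseless bait is detected as exactly two peaks and
    the raw-intensity apex is stable under the default noise level.
    """
    entities = (
        EntitySpec(label="I", apex_fraction=28, width=1.0, bait_amount=1.0e9),
        EntitySpec(label="II", apex_fraction=34, width=1.0, bait_amount=1.5e9),
    )

    def sub(pid, gene, ratios, bait=False, contam=False):
        return SubunitSpec(pid, gene, ratios, is_bait=bait, is_contaminant=contam)

    subunits = (
        sub("SYN0001", "BAIT", (1.0, 1.0), bait=True),
        sub("SYN0002", "CORE1", (1.0, 1.0)),
        sub("SYN0003", "CORE2", (0.9, 0.9)),
        sub("SYN0004", "CORE3", (1.2, 1.2)),
        sub("SYN0005", "CORE4", (0.8, 0.8)),
        sub("SYN0006", "CORE5", (1.1, 1.1)),
        sub("SYN0007", "CORE6", (0.7, 0.7)),
        sub("SYN0008", "CORE7", (1.0, 1.0)),
        sub("SYN0009", "HIENR1", (0.5, 1.0)),
        sub("SYN0010", "HIENR2", (0.45, 0.9)),
        sub("SYN0011", "HIENR3", (0.6, 1.2)),
        sub("SYN0012", "PBOTH1", (1.0, 1.0)),
        sub("SYN0013", "P2ONLY1", (0.0, 1.0)),
        sub("SYN0014", "P2ONLY2", (0.0, 0.8)),
        sub("SYN0015", "P1ONLY1", (0.6, 0.0)),
        sub("SYN0016", "CONT1", (0.0, 0.0), contam=True),
        sub("SYN0017", "CONT2", (0.0, 0.0), contam=True),
        sub("SYN0018", "CONT3", (0.0, 0.0), contam=True),
        sub("SYN0019", "CONT4", (0.0, 0.0), contam=True),
        sub("SYN0020", "CONT5", (0.0, 0.0), contam=True),
        sub("SYN0021", "CONT6", (0.0, 0.0), contam=True),
    )
    return SyntheticTruth(
        n_fractions=48,
        entities=entities,
        subunits=subunits,
        noise_cv=noise_cv,
        dropout_rate=dropout_rate,
        replicate_shift=replicate_shift,
        seed=seed,
    )


def expected_intensity(truth: SyntheticTruth, replicate: int = 1) -> np.ndarray:
    """Noiseless expected intensity matrix, shape (n_subunits, n_fractions).

    Contaminant rows are zero here; their unstructured signal is added only
    in :func:`simulate_table`.
    """
    _check_replicate(replicate)
    shift = truth.replicate_shift if replicate == 2 else 0
    fractions = np.arange(1, truth.n_fractions + 1, dtype=float)
    out = np.zeros((len(truth.subunits), truth.n_fractions))
    for i, sub in enumerate(truth.subunits):
        if sub.is_contaminant:
            continue
        for e, ent in enumerate(truth.entities):
            mu = ent.apex_fraction + shift
            out[i] += (
                sub.per_entity_ratio[e]
                * ent.bait_amount
                * np.exp(-((fractions - mu) ** 2) / (2.0 * ent.width**2))
            )
    return out


def peptide_counts(truth: SyntheticTruth) -> np.ndarray:
    """Per-protein theoretical-peptide counts, deterministic in the seed only."""
    rng = np.random.default_rng([truth.seed, _PEPCOUNT_STREAM])
    return rng.integers(5, 61, size=len(truth.subunits))


def _check_replicate(replicate: int) -> None:
    if replicate not in (1, 2):
        raise ValueError(f"replicate must be 1 or 2, got {replicate!r}")


def simulate_table(truth: SyntheticTruth, replicate: int = 1) -> QuantTable:
    """Simulate one replicate's quantitation table from *truth*.

    Deterministic in ``(truth, replicate)``: the replicate index seeds an
    independent noise stream so the two replicates differ in noise, dropout
    and contaminant structure but share peptide counts.
    """
    _check_replicate(replicate)
    signal = expected_intensity(truth, replicate)

    contam_rows = [i for i, s in enumerate(truth.subunits) if s.is_contaminant]
    if contam_rows:
        crng = np.random.default_rng([truth.seed, _CONTAM_STREAM, replicate])
        base = max(ent.bait_amount for ent in truth.entities)
        # spiky, unstructured: heavy-tailed log-normal draws per cell
        signal[contam_rows] = 0.02 * base * crng.lognormal(
            mean=0.0, sigma=1.5, size=(len(contam_rows), truth.n_fractions)
        )

    rng = np.random.default_rng([truth.seed, _NOISE_STREAM, replicate])
    if truth.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(truth.noise_cv**2)))
        factors = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=signal.shape)
    else:
        factors = np.ones_like(signal)
        rng.lognormal(mean=0.0, sigma=1.0, size=signal.shape)  # keep stream position fixed
    intensity = signal * factors

    if truth.dropout_rate > 0:
        drop = rng.random(size=signal.shape) < truth.dropout_rate
        intensity = np.where(drop, 0.0, intensity)
    else:
        rng.random(size=signal.shape)

    peps = peptide_counts(truth)
    ibaq = intensity / peps[:, None]

    return QuantTable(
        protein_ids=[s.protein_id for s in truth.subunits],
        gene_names=[s.gene_name for s in truth.subunits],
        intensity=intensity,
        ibaq=ibaq,
        flag_contaminant=np.array([s.is_contaminant for s in truth.subunits]),
        flag_reverse=np.zeros(len(truth.subunits), dtype=bool),
        flag_only_by_site=np.zeros(len(truth.subunits), dtype=bool),
        fraction_labels=[str(k) for k in range(1, truth.n_fractions + 1)],
    )


def default_marker_ladder(n_fractions: int = 48) -> list[tuple[int, float]]:
    """A plausible 20 kDa - 1.2 MDa ladder placing the peak region near 1 MDa."""
    mid = max(2, min(n_fractions - 1, 30))
    return [(1, 20.0), (mid, 900.0), (n_fractions, 1200.0)]


def truth_to_yaml(truth: SyntheticTruth, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "n_fractions": truth.n_fractions,
        "noise_cv": truth.noise_cv,
        "dropout_rate": truth.dropout_rate,
        "replicate_shift": truth.replicate_shift,
        "seed": truth.seed,
        "entities": [asdict(e) for e in truth.entities],
        "subunits": [
            {**asdict(s), "per_entity_ratio": list(s.per_entity_ratio)} for s in truth.subunits
        ],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def truth_from_yaml(path: str | Path) -> SyntheticTruth:
    doc = yaml.safe_load(Path(path).read_text())
    return SyntheticTruth(
        n_fractions=int(doc["n_fractions"]),
        entities=tuple(EntitySpec(**e) for e in doc["entities"]),
        subunits=tuple(
            SubunitSpec(
                protein_id=s["protein_id"],
                gene_name=s["gene_name"],
                per_entity_ratio=tuple(s["per_entity_ratio"]),
                is_bait=s["is_bait"],
                is_contaminant=s["is_contaminant"],
            )
            for s in doc["subunits"]
        ),
        noise_cv=float(doc["noise_cv"]),
        dropout_rate=float(doc["dropout_rate"]),
        replicate_shift=int(doc["replicate_shift"]),
        seed=int(doc["seed"]),
    )


def write_fixture(truth: SyntheticTruth, directory: str | Path) -> dict[str, object]:
    """Write a complete test fixture: two replicate tables, the truth spec,
    a marker ladder, and per-entity membership gene lists.

    Returns a manifest mapping artifact names to written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, object] = {}
    tables = []
    for rep in (1, 2):
        p = directory / f"quant_replicate{rep}.tsv"
        write_quant_table(simulate_table(truth, rep), p)
        tables.append(str(p))
    manifest["quant_tables"] = tables
    manifest["truth"] = str(truth_to_yaml(truth, directory / "truth.yaml"))
    manifest["marker_ladder"] = str(
        write_marker_ladder(default_marker_ladder(truth.n_fractions), directory / "marker_ladder.tsv")
    )

    gene_lists = {}
    for e, ent in enumerate(truth.entities):
        p = directory / f"genes_entity_{ent.label}.txt"
        genes = [
            s.gene_name for s in truth.subunits if not s.is_contaminant and s.per_entity_ratio[e] > 0
        ]
        p.write_text("\n".join(genes) + "\n")
        gene_lists[ent.label] = str(p)
    manifest["gene_lists"] = gene_lists
    return manifest
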