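"""Synthetic expression data with planted modules, complexes, hubs and low-information genes.

The generator emulates a 20-time-point microarray survey of the
*Tetrahymena* life cycle: three growth densities (``L-l``, ``L-m``,
``L-h``), seven starvation time points (``S-0`` … ``S-24``) and ten
conjugation time points (``C-0`` … ``C-18``). Genes are drawn from

* planted coexpression modules — each gene is its module's latent log2
  profile plus i.i.d. Gaussian noise;
* planted complexes — subsets of a module whose members get attenuated
  noise, making them the tightest cliques in the data (the ground-truth
  "protein complexes" for benchmark validation);
* background genes — i.i.d. noise around a constant moderate expression
  level, with no planted structure;
* low-information genes — flat, dimly expressed rows whose between-sample
  range and mean both fall below the global medians by construction, so the
  combined low-information filter removes exactly these.

The default design ships six latent profile shapes matching the six
stage-specific hub classes observed in the real life cycle
(conjugation-early, conjugation-late, growth-specific, starvation-shared,
mixed/oscillating, uniformly-high), so hub-group recovery maps onto the six
planted modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .benchmark import ComplexBenchmark
from .enrichment import AnnotationMap
from .errors import ValidationError

__all__ = [
    "LIFE_CYCLE_LABELS",
    "ComplexSpec",
    "SyntheticDesign",
    "SyntheticTruth",
    "default_design",
    "generate_dataset",
    "generate_complex_benchmark",
    "generate_annotation_map",
]

#: The 20 life-cycle stage labels: growth (3), starvation (7), conjugation (10).
LIFE_CYCLE_LABELS: tuple[str, ...] = (
    "L-l", "L-m", "L-h",
    "S-0", "S-3", "S-6", "S-9", "S-12", "S-15", "S-24",
    "C-0", "C-2", "C-4", "C-6", "C-8", "C-10", "C-12", "C-14", "C-16", "C-18",
)


@dataclass(frozen=True)
class ComplexSpec:
    """A planted complex: ``size`` genes inside module ``module`` whose noise
    sd is multiplied by ``noise_attenuation`` (< 1 ⇒ tighter than the module)."""

    name: str
    module: int
    size: int
    noise_attenuation: float = 0.5


@dataclass(frozen=True)
class SyntheticDesign:
    """Full specification of a synthetic dataset; see the module docstring.

    ``module_profiles[k]`` is module k's latent mean log2 expression over
    ``sample_labels``. ``background_mean`` sets the constant level of the
    unstructured background genes (chosen moderately high so that they pass
    the mean condition of the low-information filter — they are noisy but
    expressed). ``low_info_level`` and ``low_info_noise_sd`` shape the flat
    dim rows. All randomness derives from ``seed``.
    """

    module_sizes: tuple[int, ...]
    module_profiles: tuple[tuple[float, ...], ...]
    complex_specs: tuple[ComplexSpec, ...] = ()
    n_background: int = 0
    n_low_info: int = 0
    noise_sd: float = 0.5
    background_mean: float = 10.0
    low_info_level: float = 4.0
    low_info_noise_sd: float = 0.05
    sample_labels: tuple[str, ...] = LIFE_CYCLE_LABELS
    seed: int = 0

    def __post_init__(self):
        if len(self.module_profiles) != len(self.module_sizes):
            raise ValidationError("one profile per module is required")
        for prof in self.module_profiles:
            if len(prof) != len(self.sample_labels):
                raise ValidationError("profile length must equal the sample count")
        if any(s < 0 for s in self.module_sizes) or self.n_background < 0 or self.n_low_info < 0:
            raise ValidationError("sizes must be >= 0")
        if self.noise_sd < 0 or self.low_info_noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")
        for spec in self.complex_specs:
            if not 0 <= spec.module < len(self.module_sizes):
                raise ValidationError(f"complex {spec.name!r} references module {spec.module}")
            if spec.size < 2:
                raise ValidationError(f"complex {spec.name!r} needs >= 2 genes")
            if not 0 <= spec.noise_attenuation:
                raise ValidationError("noise_attenuation must be >= 0")
        taken: dict[int, int] = {}
        for spec in self.complex_specs:
            taken[spec.module] = taken.get(spec.module, 0) + spec.size
        for mod, used in taken.items():
            if used > self.module_sizes[mod]:
                raise ValidationError(
                    f"complexes in module {mod} need {used} genes, module has "
                    f"{self.module_sizes[mod]}"
                )

    @property
    def n_genes(self) -> int:
        return sum(self.module_sizes) + self.n_background + self.n_low_info


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated dataset.

    ``module_of`` maps every gene to ``"M<k>"`` (1-based planted module id),
    ``"background"`` or ``"low-info"``; ``complexes`` are the planted gene
    sets (each a subset of one module); ``profile_of`` the latent vectors.
    """

    module_of: dict
    complexes: dict
    profile_of: dict
    seed: int

    def module_genes(self, k: int) -> frozenset:
        tag = f"M{k}"
        return frozenset(g for g, m in self.module_of.items() if m == tag)


def _stage_profile(base: float, bumps: dict[str, float]) -> tuple[float, ...]:
    return tuple(base + bumps.get(lbl, 0.0) for lbl in LIFE_CYCLE_LABELS)


def default_design(seed: int = 0, noise_sd: float = 0.5) -> SyntheticDesign:
    """The package's default study-conditions design: 600 genes × 20 samples.

    Six planted modules (120/100/90/80/70/60 genes) carry the six
    stage-profile shapes; two complexes of 19 and 13 genes (sizes echoing
    the 19S regulatory and 20S core proteasome particles) are planted in the
    conjugation-early and conjugation-late modules with noise attenuation
    0.5; 30 unstructured background genes and 50 low-information genes
    complete the 600. The two conjugation modules carry the largest
    expression swings so that the planted complexes sit clearly above the
    median between-sample range and are never lost to the low-information
    filter.
    """
    conj_early = {f"C-{h}": 6.0 for h in (0, 2, 4, 6, 8)}
    conj_late = {f"C-{h}": 6.0 for h in (10, 12, 14, 16, 18)}
    growth = {lbl: 4.0 for lbl in ("L-l", "L-m", "L-h")}
    starv_shared = {f"S-{h}": 3.0 for h in (0, 3, 6, 9, 12, 15, 24)}
    starv_shared.update({"C-0": 2.0, "C-2": 2.0, "C-4": 2.0})
    mixed = {lbl: (1.5 if i % 2 == 0 else -1.5) for i, lbl in enumerate(LIFE_CYCLE_LABELS)}
    profiles = (
        _stage_profile(7.0, conj_early),      # M1: conjugation-early
        _stage_profile(7.0, conj_late),       # M2: conjugation-late
        _stage_profile(7.0, growth),          # M3: growth-specific
        _stage_profile(7.0, starv_shared),    # M4: starvation-shared
        _stage_profile(8.0, mixed),           # M5: mixed / oscillating
        _stage_profile(11.0, {}),             # M6: uniformly high
    )
    return SyntheticDesign(
        module_sizes=(120, 100, 90, 80, 70, 60),
        module_profiles=profiles,
        complex_specs=(
            ComplexSpec("complex-19S-like", module=0, size=19, noise_attenuation=0.5),
            ComplexSpec("complex-20S-like", module=1, size=13, noise_attenuation=0.5),
        ),
        n_background=30,
        n_low_info=50,
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_dataset(design: SyntheticDesign) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw one expression matrix (and its ground truth) from a design.

    Deterministic: the same design (including seed) always yields a bitwise
    identical matrix. Gene ids are ``SYN0001`` … in module, background,
    low-info order.
    """
    rng = np.random.default_rng(design.seed)
    n_samples = len(design.sample_labels)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    module_of: dict[str, str] = {}
    complexes: dict[str, set] = {spec.name: set() for spec in design.complex_specs}

    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"SYN{counter:04d}"

    for k, (size, profile) in enumerate(zip(design.module_sizes, design.module_profiles)):
        profile = np.asarray(profile, dtype=float)
        # complex members occupy the first genes of their module
        specs = [s for s in design.complex_specs if s.module == k]
        plan: list[tuple[str | None, float]] = []
        for spec in specs:
            plan.extend((spec.name, spec.noise_attenuation) for _ in range(spec.size))
        plan.extend((None, 1.0) for _ in range(size - len(plan)))
        for complex_name, atten in plan:
            gid = next_id()
            gene_ids.append(gid)
            module_of[gid] = f"M{k + 1}"
            if complex_name is not None:
                complexes[complex_name].add(gid)
            rows.append(profile + rng.normal(0.0, design.noise_sd * atten, n_samples))

    for _ in range(design.n_background):
        gid = next_id()
        gene_ids.append(gid)
        module_of[gid] = "background"
        rows.append(design.background_mean + rng.normal(0.0, design.noise_sd, n_samples))

    for _ in range(design.n_low_info):
        gid = next_id()
        gene_ids.append(gid)
        module_of[gid] = "low-info"
        rows.append(design.low_info_level + rng.normal(0.0, design.low_info_noise_sd, n_samples))

    m = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, n_samples)),
        index=pd.Index(gene_ids, name="gene"),
        columns=list(design.sample_labels),
    )
    truth = SyntheticTruth(
        module_of=module_of,
        complexes={name: frozenset(g) for name, g in complexes.items()},
        profile_of={f"M{k + 1}": tuple(p) for k, p in enumerate(design.module_profiles)},
        seed=design.seed,
    )
    return m, truth


def generate_complex_benchmark(truth: SyntheticTruth) -> ComplexBenchmark:
    """Emit the planted complexes as a clique benchmark (GMT-serialisable)."""
    if not truth.complexes:
        raise ValidationError("truth contains no planted complexes")
    return ComplexBenchmark.from_gene_sets(
        {name: set(members) for name, members in truth.complexes.items()}
    )


def generate_annotation_map(
    truth: SyntheticTruth,
    terms_per_module: int = 2,
    background_term_rate: float = 0.0,
) -> AnnotationMap:
    """Module-dedicated annotation terms, plus optional background noise terms.

    Each planted module ``M<k>`` receives ``terms_per_module`` dedicated
    terms (``M<k>:term<j>``) annotating every gene of that module; every
    non-member gene independently receives each term with probability
    ``background_term_rate``. Deterministic under ``truth.seed``.
    """
    if terms_per_module < 1:
        raise ValidationError("terms_per_module must be >= 1")
    if not 0.0 <= background_term_rate <= 1.0:
        raise ValidationError("background_term_rate must be in [0, 1]")
    rng = np.random.default_rng((truth.seed, 0xA110))
    genes = sorted(truth.module_of)
    modules = sorted({m for m in truth.module_of.values() if m.startswith("M")},
                     key=lambda s: int(s[1:]))
    mapping: dict[str, set] = {}
    for mod in modules:
        members = {g for g in genes if truth.module_of[g] == mod}
        for j in range(1, terms_per_module + 1):
            term = f"{mod}:term{j}"
            for g in members:
                mapping.setdefault(g, set()).add(term)
            if background_term_rate > 0.0:
                outsiders = [g for g in genes if g not in members]
                draws = rng.random(len(outsiders)) < background_term_rate
                for g, hit in zip(outsiders, draws):
                    if hit:
                        mapping.setdefault(g, set()).add(term)
    return AnnotationMap(mapping)
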