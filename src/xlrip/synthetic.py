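"""Ground-truth-labeled synthetic inputs for every pipeline stage.

Three generators, all pure functions of (spec, seed):

* ``simulate_csms`` — CSM tables whose incorrect matches follow the
  k-fold-decoy composition: each wrongly identified peptide is decoy with
  probability k/(k+1) and target with probability 1/(k+1), independently.
  Incorrect CSMs come in two kinds — one wrong peptide (the other peptide
  correct, hence target) and both peptides wrong — which is exactly the
  distinction the tf/ff error model estimates from TD and DD counts.
  Feature vectors are class-conditional Gaussians, identical for all wrong
  matches regardless of decoy class (the core target-decoy assumption).

* ``simulate_structure_and_links`` — a toy multi-chain structure plus a
  link table in which true links are planted below the distance cutoff,
  violating links above it, and unmappable links reference residues absent
  from the coordinates.

* ``simulate_counts`` — negative-binomial RIP-seq count matrices with a
  replicate structure and per-annotation-class multiplicative IP
  enrichment (multi-pass membrane transcripts up, single-pass down,
  soluble depleted in both IPs), emitted jointly with the matching sample
  sheet and transcript annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .csm import CSMRecord, PeptideMatch
from .errors import ConfigError
from .fdr import CrossLink
from .ripseq import CountMatrix, SampleSheet
from .structure import ChainMap, ChainMapEntry, StructureModel

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# CSM simulation
# ---------------------------------------------------------------------------


@dataclass
class FeatureModel:
    """Class-conditional distribution of CSM features (Gaussian locations/scales)."""

    score_mean: float
    score_sd: float
    diff_mean: float
    diff_sd: float
    pct_ions_mean: float
    pct_ions_sd: float
    charge_probs: dict[int, float]
    rank_probs: dict[int, float]
    length_range: tuple[int, int]


#: Correct matches: confident scores, large score difference, many matched ions.
CORRECT_FEATURES = FeatureModel(
    score_mean=42.0,
    score_sd=6.0,
    diff_mean=13.0,
    diff_sd=4.0,
    pct_ions_mean=0.55,
    pct_ions_sd=0.12,
    charge_probs={3: 0.35, 4: 0.35, 5: 0.20, 6: 0.10},
    rank_probs={1: 0.9, 2: 0.1},
    length_range=(6, 21),
)

#: Incorrect matches: near the prefilter floor, small difference, fewer ions.
INCORRECT_FEATURES = FeatureModel(
    score_mean=27.0,
    score_sd=4.0,
    diff_mean=2.5,
    diff_sd=2.2,
    pct_ions_mean=0.33,
    pct_ions_sd=0.10,
    charge_probs={3: 0.40, 4: 0.30, 5: 0.20, 6: 0.10},
    rank_probs={1: 0.40, 2: 0.25, 3: 0.15, 4: 0.10, 5: 0.10},
    length_range=(4, 26),
)


@dataclass
class CSMSimSpec:
    """Conditions of a synthetic CSM search output.

    ``frac_one_wrong`` splits the incorrect CSMs between matches with
    exactly one wrong peptide (the other correct, hence always target) and
    matches with both peptides wrong.  ``n_true_pairs`` controls how many
    unique residue pairs the correct CSMs share, so aggregation to links
    has real multiplicity.  ``decoy_bias`` (robustness knob, default 0)
    shifts the feature means of decoy-containing wrong matches away from
    the TT wrong matches, violating the target-decoy assumption on demand.
    """

    n_true: int = 2000
    n_false: int = 20000
    k: float = 10.0
    frac_one_wrong: float = 0.5
    channel_mix: dict = field(default_factory=lambda: {"ETD": 0.5, "HCD": 0.5})
    correct: FeatureModel = field(default_factory=lambda: CORRECT_FEATURES)
    incorrect: FeatureModel = field(default_factory=lambda: INCORRECT_FEATURES)
    n_true_pairs: int | None = None
    n_proteins: int = 20
    protein_length: int = 400
    decoy_bias: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true < 0 or self.n_false < 0:
            raise ConfigError("n_true and n_false must be nonnegative")
        if self.n_true + self.n_false == 0:
            raise ConfigError("need at least one CSM to simulate")
        if self.k <= 0:
            raise ConfigError("k must be positive")
        if not 0.0 <= self.frac_one_wrong <= 1.0:
            raise ConfigError("frac_one_wrong must be in [0, 1]")
        if abs(sum(self.channel_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("channel_mix must sum to 1")


def _draw_choice(rng: np.random.Generator, probs: dict, n: int) -> np.ndarray:
    keys = np.array(sorted(probs))
    p = np.array([probs[k] for k in keys], dtype=float)
    return rng.choice(keys, size=n, p=p / p.sum())


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def simulate_csms(spec: CSMSimSpec) -> tuple[list[CSMRecord], pd.DataFrame]:
    """Draw a labeled CSM set.

    Returns ``(records, truth)`` where ``truth`` has one row per record
    (same order) with columns spectrum_id, is_correct, n_wrong_peptides.
    Correct matches are always TT; each wrong peptide is decoy with
    probability k/(k+1) independently.
    """
    rng_class, rng_feat, rng_pep = _child_seeds(spec.rng_seed, 3)
    n_one_wrong = int(round(spec.n_false * spec.frac_one_wrong))
    n_two_wrong = spec.n_false - n_one_wrong
    n = spec.n_true + spec.n_false

    kinds = np.array(
        [0] * spec.n_true + [1] * n_one_wrong + [2] * n_two_wrong
    )  # number of wrong peptides
    rng_class.shuffle(kinds)

    p_decoy = spec.k / (spec.k + 1.0)
    channels = _draw_choice(
        rng_class, {c: f for c, f in spec.channel_mix.items() if f > 0}, n
    )

    # Pool of true residue pairs so correct CSMs repeat pairs (links with
    # n_csms > 1), as repeated observation of real cross-links does.
    n_pairs = spec.n_true_pairs or max(1, spec.n_true // 3)
    target_ids = [f"P{i:03d}" for i in range(spec.n_proteins)]
    n_decoy_proteins = max(1, int(round(spec.k * spec.n_proteins)))
    decoy_ids = [f"DECOY{i:03d}" for i in range(n_decoy_proteins)]
    pair_pool = []
    seen = set()
    while len(pair_pool) < n_pairs:
        pa, pb = rng_pep.choice(target_ids, size=2)
        ra = int(rng_pep.integers(1, spec.protein_length + 1))
        rb = int(rng_pep.integers(1, spec.protein_length + 1))
        key = ((pa, ra), (pb, rb))
        if key not in seen and (pa, ra) != (pb, rb):
            seen.add(key)
            pair_pool.append(key)

    def draw_features(model: FeatureModel, m: int) -> dict[str, np.ndarray]:
        return {
            "score1": rng_feat.normal(model.score_mean, model.score_sd, m),
            "score2": rng_feat.normal(model.score_mean, model.score_sd, m),
            "diff": rng_feat.normal(model.diff_mean, model.diff_sd, m),
            "pct": np.clip(
                rng_feat.normal(model.pct_ions_mean, model.pct_ions_sd, m), 0.01, 1.0
            ),
            "charge": _draw_choice(rng_feat, model.charge_probs, m),
            "rank1": _draw_choice(rng_feat, model.rank_probs, m),
            "rank2": _draw_choice(rng_feat, model.rank_probs, m),
            "len1": rng_feat.integers(*model.length_range, size=m),
            "len2": rng_feat.integers(*model.length_range, size=m),
        }

    feats_true = draw_features(spec.correct, n)
    feats_false = draw_features(spec.incorrect, n)

    records: list[CSMRecord] = []
    truth_rows = []
    for i in range(n):
        n_wrong = int(kinds[i])
        f = feats_true if n_wrong == 0 else feats_false
        sid = f"spec{i:06d}"
        wrong_flags = [False, False]
        if n_wrong == 1:
            wrong_flags[int(rng_pep.integers(0, 2))] = True
        elif n_wrong == 2:
            wrong_flags = [True, True]

        sides = []
        if n_wrong == 0:
            (pa, ra), (pb, rb) = pair_pool[int(rng_pep.integers(0, n_pairs))]
            sides = [(pa, ra, False), (pb, rb, False)]
        else:
            for wrong in wrong_flags:
                if not wrong:
                    pa, ra = pair_pool[int(rng_pep.integers(0, n_pairs))][0]
                    sides.append((pa, ra, False))
                else:
                    is_decoy = bool(rng_pep.random() < p_decoy)
                    pool = decoy_ids if is_decoy else target_ids
                    pid = pool[int(rng_pep.integers(0, len(pool)))]
                    pos = int(rng_pep.integers(1, spec.protein_length + 1))
                    sides.append((pid, pos, is_decoy))

        bias = spec.decoy_bias if (n_wrong and any(s[2] for s in sides)) else 0.0
        peps = []
        for j, (pid, pos, is_decoy) in enumerate(sides, start=1):
            length = int(f[f"len{j}"][i])
            peps.append(
                PeptideMatch(
                    sequence=_random_peptide(rng_pep, length),
                    protein_id=pid,
                    link_pos=pos,
                    is_decoy=is_decoy,
                    rank=int(f[f"rank{j}"][i]),
                    length=length,
                    score=float(f[f"score{j}"][i]),
                )
            )
        records.append(
            CSMRecord(
                spectrum_id=sid,
                channel=str(channels[i]),
                pep1=peps[0],
                pep2=peps[1],
                score_diff=float(f["diff"][i] + bias),
                percent_ions_matched=float(f["pct"][i]),
                precursor_charge=int(f["charge"][i]),
            )
        )
        truth_rows.append(
            {"spectrum_id": sid, "is_correct": n_wrong == 0, "n_wrong_peptides": n_wrong}
        )
    truth = pd.DataFrame(truth_rows)
    return records, truth


# ---------------------------------------------------------------------------
# Structure simulation
# ---------------------------------------------------------------------------


@dataclass
class StructureSimSpec:
    """A toy structure with links planted at known distances.

    True links get a minimum Cα–Cα distance drawn inside
    ``true_distance_range`` (below the cutoff), violating links inside
    ``violating_distance_range`` (above it), so the planted violation
    fraction is ``n_links_violating / (n_links_true + n_links_violating)``
    by construction.  Unmappable links reference residue numbers beyond
    the modeled chains.
    """

    n_chains: int = 4
    residues_per_chain: int = 60
    n_links_true: int = 18
    n_links_violating: int = 2
    n_links_unmappable: int = 2
    true_distance_range: tuple[float, float] = (8.0, 30.0)
    violating_distance_range: tuple[float, float] = (40.0, 60.0)
    distance_cutoff: float = 35.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.residues_per_chain < 2:
            raise ConfigError("need at least one chain with two residues")
        if min(self.n_links_true, self.n_links_violating, self.n_links_unmappable) < 0:
            raise ConfigError("link counts must be nonnegative")
        if self.true_distance_range[1] >= self.distance_cutoff:
            raise ConfigError("true_distance_range must lie below the cutoff")
        if self.violating_distance_range[0] <= self.distance_cutoff:
            raise ConfigError("violating_distance_range must lie above the cutoff")
        needed = 2 * (self.n_links_true + self.n_links_violating)
        if needed > self.n_chains * self.residues_per_chain:
            raise ConfigError("not enough residues to host the requested links")


#: Grid spacing for unrelated residues; any non-planted pair is >= this apart.
_CELL = 150.0


def simulate_structure_and_links(
    spec: StructureSimSpec, pdb_path: str | Path | None = None
) -> tuple[StructureModel, ChainMap, list[CrossLink], pd.DataFrame]:
    """Build the toy structure, its chain map, links, and the truth table.

    Chains are named A, B, ...; chain ``X`` models protein ``PROTX`` with
    residue offset 0.  Every residue gets its own cell on a coarse 3-D
    grid (>= 150 Å apart), then each planted link moves its second residue
    next to its first at the drawn distance; link endpoints are never
    reused, so each link's minimum distance is exactly the planted one.
    Truth columns: link index, kind (true/violating/unmappable),
    planted_distance (NaN for unmappable).  Coordinates are rounded to
    3 decimals (PDB fixed-width precision) before distances are planted.
    If ``pdb_path`` is given the structure is also written there.
    """
    rng = np.random.default_rng(spec.rng_seed)
    chain_names = [chr(ord("A") + i) for i in range(spec.n_chains)]
    residues = [
        (c, r) for c in chain_names for r in range(1, spec.residues_per_chain + 1)
    ]

    # One grid cell per residue; jitter inside a 20 Å box keeps geometry
    # irregular while inter-cell distances stay >= _CELL - 2*20 >> cutoff.
    side = int(np.ceil(len(residues) ** (1 / 3)))
    coords: dict[tuple[str, int], np.ndarray] = {}
    for idx, key in enumerate(residues):
        cell = np.array([idx % side, (idx // side) % side, idx // side**2], dtype=float)
        coords[key] = np.round(cell * _CELL + rng.uniform(0.0, 20.0, size=3), 3)

    order = list(residues)
    rng.shuffle(order)
    slots = iter(order)

    links: list[CrossLink] = []
    truth_rows = []

    def plant(n: int, lo: float, hi: float, kind: str) -> None:
        for _ in range(n):
            (c1, r1), (c2, r2) = next(slots), next(slots)
            d = rng.uniform(lo, hi)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            coords[(c2, r2)] = np.round(coords[(c1, r1)] + d * u, 3)
            planted = float(np.linalg.norm(coords[(c2, r2)] - coords[(c1, r1)]))
            links.append(
                CrossLink(
                    protein_a=f"PROT{c1}",
                    residue_a=r1,
                    protein_b=f"PROT{c2}",
                    residue_b=r2,
                    best_svm_score=float(rng.uniform(1.5, 5.0)),
                    channel_of_best="HCD",
                    n_csms=1,
                    decoy_class="TT",
                )
            )
            truth_rows.append({"kind": kind, "planted_distance": planted})

    plant(spec.n_links_true, *spec.true_distance_range, kind="true")
    plant(spec.n_links_violating, *spec.violating_distance_range, kind="violating")
    for _ in range(spec.n_links_unmappable):
        c1 = chain_names[int(rng.integers(0, spec.n_chains))]
        c2 = chain_names[int(rng.integers(0, spec.n_chains))]
        # Residue numbers beyond the chain: absent from the structure.
        links.append(
            CrossLink(
                protein_a=f"PROT{c1}",
                residue_a=spec.residues_per_chain + int(rng.integers(10, 100)),
                protein_b=f"PROT{c2}",
                residue_b=int(rng.integers(1, spec.residues_per_chain + 1)),
                best_svm_score=float(rng.uniform(1.5, 5.0)),
                channel_of_best="HCD",
                n_csms=1,
                decoy_class="TT",
            )
        )
        truth_rows.append({"kind": "unmappable", "planted_distance": np.nan})

    model = StructureModel(
        chains={
            c: {r: coords[(c, r)] for r in range(1, spec.residues_per_chain + 1)}
            for c in chain_names
        },
        source_id="synthetic",
    )
    chain_map = ChainMap(
        [ChainMapEntry(protein_id=f"PROT{c}", chain_id=c) for c in chain_names]
    )
    if pdb_path is not None:
        write_structure_pdb(model, pdb_path)
    truth = pd.DataFrame(truth_rows)
    truth.insert(0, "link_index", np.arange(len(truth)))
    return model, chain_map, links, truth


def write_structure_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a Cα-only PDB (one ALA residue per coordinate) via gemmi."""
    st = gemmi.Structure()
    st.name = model.source_id or "synthetic"
    gm = gemmi.Model("1")
    for chain_id in sorted(model.chains):
        chain = gemmi.Chain(chain_id)
        for resnum in sorted(model.chains[chain_id]):
            xyz = model.chains[chain_id][resnum]
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(resnum), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------


@dataclass
class ClassEffect:
    """Per-annotation-class abundance scaling in the two IP roles.

    ``flag_factor``/``ctrl_factor`` multiply the gene's baseline (input)
    abundance in the Flag and control IPs.  The expected enrichment score
    of the class is ``flag_factor - ctrl_factor``.
    """

    flag_factor: float
    ctrl_factor: float
    fraction: float  # fraction of genes in this class
    tmd_choices: tuple[int, ...] = ()  # empty = soluble (0 TMDs)
    categories: tuple[str, ...] = ("other",)


#: Default class mix: ribosome-membrane IPs deplete soluble messages, carry
#: a nonspecific membrane background, and specifically enrich multi-pass
#: (>= 4 TMD) clients, mirroring a translocon-biased elution.
DEFAULT_EFFECTS = {
    "soluble": ClassEffect(0.05, 0.05, 0.60, (), ("soluble",)),
    "single_pass": ClassEffect(0.15, 0.10, 0.20, (1,), ("receptor", "other")),
    "few_pass": ClassEffect(0.60, 0.10, 0.08, (2, 3), ("enzyme", "other")),
    "multi_pass": ClassEffect(
        3.10,
        0.10,
        0.12,
        (4, 5, 6, 7, 8, 9, 10, 11, 12, 14),
        ("transporter", "receptor", "channel", "hydrolase"),
    ),
}


@dataclass
class CountSimSpec:
    """Conditions of a synthetic RIP-seq experiment.

    Three Flag-IP and three control-IP replicates with two input
    (total-membrane) replicates; negative-binomial counts with dispersion
    ``dispersion`` (Var = m + dispersion·m²) around log-normal baseline
    abundances.  Expected library size is equalized across samples so
    planted per-class enrichment is recovered on the CPM scale.
    """

    n_genes: int = 4000
    replicates: dict = field(
        default_factory=lambda: {"flag_ip": 3, "ctrl_ip": 3, "input": 2}
    )
    dispersion: float = 0.10
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.3
    library_size: float = 3.0e6
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if any(r < 1 for r in self.replicates.values()):
            raise ConfigError("each role needs at least one replicate")
        total = sum(e.fraction for e in self.effects.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("class fractions must sum to 1")


def simulate_counts(
    spec: CountSimSpec,
) -> tuple[CountMatrix, SampleSheet, pd.DataFrame]:
    """Draw the count matrix, sample sheet, and transcript annotation.

    The annotation carries the hidden class label (column ``sim_class``)
    and the planted per-gene expected enrichment (``planted_enrichment``),
    so downstream recovery is checkable against generating parameters.
    """
    rng_assign, rng_base, rng_counts = _child_seeds(spec.rng_seed, 3)

    class_names = sorted(spec.effects)
    fractions = np.array([spec.effects[c].fraction for c in class_names])
    classes = rng_assign.choice(class_names, size=spec.n_genes, p=fractions)
    genes = [f"GENE{i:05d}" for i in range(spec.n_genes)]

    baseline = rng_base.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)

    flag_mu = np.empty(spec.n_genes)
    ctrl_mu = np.empty(spec.n_genes)
    for i, cls in enumerate(classes):
        eff = spec.effects[cls]
        flag_mu[i] = baseline[i] * eff.flag_factor
        ctrl_mu[i] = baseline[i] * eff.ctrl_factor

    # CPM renormalizes each sample to its own total, so the enrichment a
    # perfect analysis recovers is the class factor divided by the
    # library-composition mean of that role's factors — computable exactly
    # from the generating parameters.
    w_flag = flag_mu.sum() / baseline.sum()
    w_ctrl = ctrl_mu.sum() / baseline.sum()

    annot_rows = []
    for i, cls in enumerate(classes):
        eff = spec.effects[cls]
        n_tmd = (
            int(rng_assign.choice(np.array(eff.tmd_choices))) if eff.tmd_choices else 0
        )
        annot_rows.append(
            {
                "gene_id": genes[i],
                "is_secretory_membrane": n_tmd > 0,
                "n_tmd": n_tmd,
                "category": str(rng_assign.choice(np.array(eff.categories))),
                "sim_class": cls,
                "planted_enrichment": eff.flag_factor / w_flag
                - eff.ctrl_factor / w_ctrl,
            }
        )
    annotation = pd.DataFrame(annot_rows)

    role_mu = {"flag_ip": flag_mu, "ctrl_ip": ctrl_mu, "input": baseline}
    sheet_rows = []
    data = {}
    r_shape = 1.0 / spec.dispersion
    for role in ("flag_ip", "ctrl_ip", "input"):
        # Equal expected library size per sample: planted enrichment then
        # survives CPM normalization exactly in expectation.
        mu = role_mu[role] * (spec.library_size / role_mu[role].sum())
        for rep in range(1, spec.replicates[role] + 1):
            sample = f"{role}_{rep}"
            p = r_shape / (r_shape + mu)
            data[sample] = rng_counts.negative_binomial(r_shape, p)
            sheet_rows.append({"sample_id": sample, "role": role, "replicate": rep})

    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    sheet = SampleSheet(frame=pd.DataFrame(sheet_rows))
    return CountMatrix(counts=counts, sheet=sheet), sheet, annotation
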