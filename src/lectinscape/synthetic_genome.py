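"""Synthetic genome-annotation generator with planted duplication truth.

Emulates the four pipeline inputs — gene GFF3, InterProScan-style
domain table, signal-peptide/TM topology table, MCScanX-style
collinearity file with Ks — for a soybean-like genome: 20 chromosomes,
lectin genes from nine families scattered among a large background of
non-lectin genes, with planted tandem arrays, planted collinear blocks,
and a two-component Ks mixture (recent duplicates below the saturation
threshold of 1.0, ancient ones above it).

Planted truth is constructed to be exactly recoverable by the default
detection parameters: same-family lectin genes from different planted
units are kept far enough apart (> max intervening + 1 ranks) that the
tandem detector finds precisely the planted arrays, and the Ks coin
that decides a pair's side of the threshold truncates the component
draw to that side, so the above-threshold fraction is exactly binomial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .records import CollinearPair, TandemCluster

__all__ = [
    "KsComponent",
    "SimulationConfig",
    "TruthLabels",
    "SimulatedGenome",
    "simulate",
    "table1_fixture",
    "table3_fixture",
    "theoretical_ks_moments",
    "ARCHITECTURE_TEMPLATES",
]


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent simulation configs."""


@dataclass(frozen=True)
class KsComponent:
    """One lognormal component of the Ks mixture (log-scale params)."""

    mean_log: float
    sd_log: float
    weight: float


#: Default mixture: a recent component centred near the younger
#: whole-genome duplication (median Ks ~ 0.15) and an ancient,
#: saturated component (median Ks ~ 1.6).
DEFAULT_KS_MIXTURE = (
    KsComponent(mean_log=math.log(0.15), sd_log=0.45, weight=0.8),
    KsComponent(mean_log=math.log(1.6), sd_log=0.35, weight=0.2),
)

#: Family mix among planted lectin genes, proportional to the nine
#: nonzero family sizes of the soybean survey (GNA largest, then
#: legume, LysM, ...).
DEFAULT_FAMILY_PROPORTIONS = {
    "CRA": 6 / 359,
    "EUL": 3 / 359,
    "GNA": 166 / 359,
    "hevein": 6 / 359,
    "jacalin": 5 / 359,
    "legume": 94 / 359,
    "LysM": 47 / 359,
    "Nictaba": 22 / 359,
    "ricin B": 10 / 359,
}

#: Domain-architecture templates per family (weight, tokens).  Tokens
#: follow the classifier's vocabulary: SP and TM are topology features,
#: everything else maps to an accession.  The catalogue mirrors the
#: architectures observed across the lectin families: G-type LecRLKs
#: with S-locus/PAN domains, hevein-chitinase and hevein-Barwin fusions,
#: triple-jacalin repeats, F-box fusions, GH5/GH27-ricin B fusions, and
#: truncated GNA domains.
ARCHITECTURE_TEMPLATES: dict[str, list[tuple[float, tuple[str, ...]]]] = {
    "CRA": [
        (0.8, ("SP", "CRA")),
        (0.2, ("SP", "CRA", "TM", "kinase")),
    ],
    "EUL": [
        (1.0, ("EUL",)),
    ],
    "GNA": [
        (0.45, ("SP", "GNA", "S-locus", "PAN", "TM", "kinase")),
        (0.15, ("SP", "GNA", "TM", "kinase")),
        (0.15, ("SP", "GNA")),
        (0.10, ("GNA",)),
        (0.05, ("SP", "GNA", "S-locus", "PAN", "SRK", "TM", "kinase")),
        (0.05, ("SP", "thaumatin", "GNA", "TM", "kinase")),
        (0.05, ("GNA*",)),  # truncated GNA domain
    ],
    "hevein": [
        (0.5, ("SP", "hevein", "Barwin")),
        (0.5, ("SP", "hevein", "chitinase")),
    ],
    "jacalin": [
        (0.4, ("jacalin",)),
        (0.2, ("F-box", "jacalin")),
        (0.4, ("jacalin", "jacalin", "jacalin")),
    ],
    "legume": [
        (0.55, ("SP", "legume", "TM", "kinase")),
        (0.35, ("SP", "legume")),
        (0.05, ("legume", "legume")),
        (0.05, ("RT", "legume", "TM", "kinase")),
    ],
    "LysM": [
        (0.4, ("SP", "LysM")),
        (0.35, ("SP", "LysM", "TM", "kinase")),
        (0.1, ("LysM", "LysM")),
        (0.1, ("F-box", "LysM")),
        (0.05, ("EEIG1/EHBP1", "LysM")),
    ],
    "Nictaba": [
        (0.4, ("F-box", "Nictaba")),
        (0.4, ("Nictaba",)),
        (0.2, ("Nictaba", "Nictaba")),
    ],
    "ricin B": [
        (0.5, ("SP", "GH5", "ricin B")),
        (0.5, ("SP", "GH27", "ricin B")),
    ],
}

#: Accession behind each non-topology token (the packaged placeholder
#: vocabulary of family_definitions.yaml) and a typical domain length.
TOKEN_ACCESSIONS = {
    "CRA": ("LEC_CRA", 336),
    "EUL": ("LEC_EUL", 150),
    "GNA": ("LEC_GNA", 110),
    "GNA*": ("LEC_GNA", 75),  # truncated: below 0.75 * 110
    "hevein": ("LEC_HEVEIN", 40),
    "jacalin": ("LEC_JACALIN", 130),
    "legume": ("LEC_LEGUME", 230),
    "LysM": ("LEC_LYSM", 45),
    "Nictaba": ("LEC_NICTABA", 165),
    "ricin B": ("LEC_RICINB", 120),
    "kinase": ("DOM_KINASE", 280),
    "S-locus": ("DOM_SLG", 120),
    "PAN": ("DOM_PAN", 80),
    "SRK": ("DOM_SRK", 90),
    "TIR": ("DOM_TIR", 170),
    "NB-ARC": ("DOM_NBARC", 290),
    "LRR": ("DOM_LRR", 60),
    "thaumatin": ("DOM_THAUMATIN", 200),
    "Barwin": ("DOM_BARWIN", 120),
    "chitinase": ("DOM_GH19", 240),
    "GH5": ("DOM_GH5", 300),
    "GH18": ("DOM_GH18", 300),
    "GH27": ("DOM_GH27", 350),
    "F-box": ("DOM_FBOX", 45),
    "EEIG1/EHBP1": ("DOM_EEIG1", 100),
    "RT": ("DOM_RT", 180),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic genome.

    Defaults emulate the soybean survey's scale: 20 chromosomes, 53
    planted tandem arrays of 2-5 members spaced 0-10 intervening genes
    apart, 121 collinear blocks, a two-component Ks mixture with ~16%
    of pairs above the saturation threshold (the survey excluded 32 of
    ~198 duplicates), and ~170 scattered lectin genes so that total
    lectin count lands near 359.
    """

    seed: int = 0
    n_chromosomes: int = 20
    genes_per_chromosome: int = 500
    family_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_PROPORTIONS)
    )
    n_tandem_arrays: int = 53
    tandem_array_size_range: tuple[int, int] = (2, 5)
    tandem_spacing_range: tuple[int, int] = (0, 10)
    n_collinear_blocks: int = 121
    block_size_range: tuple[int, int] = (3, 10)
    ks_distribution: tuple[KsComponent, ...] = DEFAULT_KS_MIXTURE
    fraction_ks_above_threshold: float = 0.16
    signal_peptide_rate: float = 0.6
    tm_rate: float = 0.3
    n_scattered_lectins: int = 170
    n_unplaced_lectins: int = 2
    ks_threshold: float = 1.0
    block_lectin_anchor_rate: float = 0.8

    def validate(self) -> None:
        probs = list(self.family_proportions.values())
        if any(p < 0 or p > 1 for p in probs) or not math.isclose(
            sum(probs), 1.0, abs_tol=1e-6
        ):
            raise ConfigError("family_proportions must be in [0,1] and sum to 1")
        for lo, hi, name in (
            (*self.tandem_array_size_range, "tandem_array_size_range"),
            (*self.tandem_spacing_range, "tandem_spacing_range"),
            (*self.block_size_range, "block_size_range"),
        ):
            if lo > hi:
                raise ConfigError(f"{name}: min {lo} > max {hi}")
        for rate in (
            self.fraction_ks_above_threshold,
            self.signal_peptide_rate,
            self.tm_rate,
            self.block_lectin_anchor_rate,
        ):
            if not (0.0 <= rate <= 1.0):
                raise ConfigError("rates must lie in [0, 1]")
        size_max = self.tandem_array_size_range[1]
        span = (size_max - 1) * (self.tandem_spacing_range[1] + 1) + 1
        if span > self.genes_per_chromosome:
            raise ConfigError(
                f"largest tandem array spans {span} gene slots but chromosomes "
                f"hold only {self.genes_per_chromosome} genes"
            )
        if self.block_size_range[1] > self.genes_per_chromosome:
            raise ConfigError("collinear blocks longer than a chromosome")


@dataclass
class TruthLabels:
    """Planted ground truth for one simulated genome."""

    family_by_gene: dict[str, str]
    mechanism_by_gene: dict[str, str]
    clusters: list[TandemCluster]
    collinear_pairs: list[CollinearPair]
    architecture_by_gene: dict[str, str]

    @property
    def tandem_genes(self) -> frozenset[str]:
        return frozenset(g for c in self.clusters for g in c.members)

    @property
    def segmental_genes(self) -> frozenset[str]:
        lectins = set(self.family_by_gene)
        out = set()
        for p in self.collinear_pairs:
            if p.ks is not None and p.ks <= 1.0:
                out.update({p.gene_a, p.gene_b} & lectins)
        return frozenset(out)


@dataclass
class SimulatedGenome:
    """The four input files (as text) plus the planted truth."""

    gff3: str
    domain_tsv: str
    topology_tsv: str
    collinearity_txt: str
    truth: TruthLabels

    def write(self, outdir) -> dict[str, str]:
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for name, text in (
            ("genes.gff3", self.gff3),
            ("domains.tsv", self.domain_tsv),
            ("topology.tsv", self.topology_tsv),
            ("collinearity.txt", self.collinearity_txt),
            ("truth.tsv", self.truth_tsv()),
        ):
            path = os.path.join(outdir, name)
            with open(path, "wt") as fh:
                fh.write(text)
            paths[name] = path
        return paths

    def truth_tsv(self) -> str:
        lines = ["gene_id\tfamily\tmechanism\tarchitecture"]
        for gid in sorted(self.truth.family_by_gene):
            lines.append(
                "\t".join(
                    (
                        gid,
                        self.truth.family_by_gene[gid],
                        self.truth.mechanism_by_gene[gid],
                        self.truth.architecture_by_gene.get(gid, ""),
                    )
                )
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Ks sampling
# ---------------------------------------------------------------------------


def _sample_ks(rng: np.random.Generator, config: SimulationConfig, above: bool) -> float:
    """Draw Ks from the mixture, truncated to the requested side of the
    threshold.  Components whose median sits on the requested side are
    preferred so rejection sampling terminates quickly."""
    thr = config.ks_threshold
    comps = [
        c
        for c in config.ks_distribution
        if (math.exp(c.mean_log) > thr) == above
    ] or list(config.ks_distribution)
    weights = np.array([c.weight for c in comps], dtype=float)
    weights /= weights.sum()
    comp = comps[int(rng.choice(len(comps), p=weights))]
    for _ in range(1000):
        value = float(rng.lognormal(comp.mean_log, comp.sd_log))
        if (value > thr) == above:
            return round(value, 4)
    return round(thr * (1.0001 if above else 0.9999), 4)


def theoretical_ks_moments(config: SimulationConfig) -> tuple[float, float]:
    """Mean and sd of the planted (side-truncated) Ks distribution.

    The generator first flips the above-threshold coin, then draws the
    preferred component truncated to that side; the resulting density
    is a weighted pair of one-sided truncated lognormals whose moments
    follow from the standard truncated-lognormal formulas.
    """
    thr = config.ks_threshold

    def phi(z: float) -> float:
        return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))

    def side_moments(above: bool) -> tuple[float, float]:
        comps = [
            c
            for c in config.ks_distribution
            if (math.exp(c.mean_log) > thr) == above
        ] or list(config.ks_distribution)
        total_w = sum(c.weight for c in comps)
        m1 = m2 = 0.0
        for c in comps:
            mu, sd = c.mean_log, c.sd_log
            a = (math.log(thr) - mu) / sd
            p_below = phi(a)
            p_side = (1.0 - p_below) if above else p_below
            if p_side <= 0:
                continue
            e1_num = phi(a - sd) if not above else 1.0 - phi(a - sd)
            e2_num = phi(a - 2 * sd) if not above else 1.0 - phi(a - 2 * sd)
            e1 = math.exp(mu + sd**2 / 2) * e1_num / p_side
            e2 = math.exp(2 * mu + 2 * sd**2) * e2_num / p_side
            m1 += (c.weight / total_w) * e1
            m2 += (c.weight / total_w) * e2
        return m1, m2

    f = config.fraction_ks_above_threshold
    lo1, lo2 = side_moments(False)
    hi1, hi2 = side_moments(True)
    mean = (1 - f) * lo1 + f * hi1
    second = (1 - f) * lo2 + f * hi2
    return mean, math.sqrt(max(second - mean**2, 0.0))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _gene_id(chrom_index: int, rank: int) -> str:
    return f"SYN{chrom_index:02d}G{rank:05d}"


def simulate(config: SimulationConfig) -> SimulatedGenome:
    """Generate the four inputs plus truth labels, deterministically.

    Same config + seed gives byte-identical output text.  Raises
    :class:`ConfigError` for infeasible configs (arrays longer than a
    chromosome, bad proportions, ...).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    families = sorted(config.family_proportions)
    fam_probs = np.array([config.family_proportions[f] for f in families])
    guard = max(config.tandem_spacing_range[1], 10) + 2  # same-family isolation

    # --- gene scaffold: ranks, coordinates, strands ----------------------
    n_chrom, n_per = config.n_chromosomes, config.genes_per_chromosome
    chrom_names = [f"chr{i}" for i in range(1, n_chrom + 1)]
    starts = np.zeros((n_chrom, n_per), dtype=np.int64)
    ends = np.zeros((n_chrom, n_per), dtype=np.int64)
    strands = []
    for ci in range(n_chrom):
        gaps = rng.integers(500, 8000, size=n_per)
        lengths = rng.integers(800, 5000, size=n_per)
        pos = 1
        for gi in range(n_per):
            pos += int(gaps[gi])
            starts[ci, gi] = pos
            ends[ci, gi] = pos + int(lengths[gi])
            pos = int(ends[ci, gi])
        strands.append(["+" if x < 0.5 else "-" for x in rng.random(n_per)])

    # lectin placement bookkeeping: (chrom_index, rank) -> (family, unit)
    placed: dict[tuple[int, int], tuple[str, int]] = {}

    def conflicts(ci: int, rank: int, family: str, unit: int) -> bool:
        for dr in range(-guard, guard + 1):
            hit = placed.get((ci, rank + dr))
            if hit is not None and hit[0] == family and hit[1] != unit:
                return True
            if dr == 0 and hit is not None:
                return True
        return False

    # --- planted tandem arrays ------------------------------------------
    clusters: list[TandemCluster] = []
    unit_counter = 0
    for ai in range(config.n_tandem_arrays):
        unit_counter += 1
        ok = False
        for _attempt in range(2000):
            family = families[int(rng.choice(len(families), p=fam_probs))]
            size = int(rng.integers(config.tandem_array_size_range[0],
                                    config.tandem_array_size_range[1] + 1))
            gaps_ = [
                int(rng.integers(config.tandem_spacing_range[0],
                                 config.tandem_spacing_range[1] + 1))
                for _ in range(size - 1)
            ]
            span = size + sum(gaps_)
            ci = int(rng.integers(0, n_chrom))
            if span > n_per:
                continue
            r0 = int(rng.integers(0, n_per - span + 1))
            ranks = [r0]
            for g in gaps_:
                ranks.append(ranks[-1] + g + 1)
            if any(conflicts(ci, r, family, unit_counter) for r in ranks):
                continue
            for r in ranks:
                placed[(ci, r)] = (family, unit_counter)
            clusters.append(
                TandemCluster(
                    cluster_id=f"PLANT_{ai + 1:04d}",
                    family=family,
                    chromosome=chrom_names[ci],
                    members=tuple(_gene_id(ci + 1, r) for r in ranks),
                    gaps=tuple(gaps_),
                )
            )
            ok = True
            break
        if not ok:
            raise ConfigError(
                "could not place all tandem arrays; chromosome too crowded "
                "for the configured array count/size/spacing"
            )

    # --- scattered singleton lectins ------------------------------------
    for si in range(config.n_scattered_lectins):
        unit_counter += 1
        for _attempt in range(2000):
            family = families[int(rng.choice(len(families), p=fam_probs))]
            ci = int(rng.integers(0, n_chrom))
            r = int(rng.integers(0, n_per))
            if conflicts(ci, r, family, unit_counter):
                continue
            placed[(ci, r)] = (family, unit_counter)
            break
        else:
            raise ConfigError("could not place scattered lectin genes")

    family_by_gene = {
        _gene_id(ci + 1, r): fam for (ci, r), (fam, _u) in placed.items()
    }

    # --- unplaced scaffold lectins (cannot be tandem) --------------------
    scaffold_rows = []
    for ui in range(config.n_unplaced_lectins):
        unit_counter += 1
        family = families[int(rng.choice(len(families), p=fam_probs))]
        gid = f"SYNUG{ui + 1:05d}"
        family_by_gene[gid] = family
        start = int(rng.integers(1000, 50000))
        scaffold_rows.append(
            (f"scaffold_{ui + 1}", start, start + int(rng.integers(800, 5000)),
             "+" if rng.random() < 0.5 else "-", gid)
        )

    # --- collinear blocks -------------------------------------------------
    lectin_positions = sorted(placed)
    pairs: list[CollinearPair] = []
    for bi in range(config.n_collinear_blocks):
        size = int(rng.integers(config.block_size_range[0],
                                config.block_size_range[1] + 1))
        if lectin_positions and rng.random() < config.block_lectin_anchor_rate:
            ci_a, anchor_rank = lectin_positions[
                int(rng.integers(0, len(lectin_positions)))
            ]
            offset = int(rng.integers(0, size))
            a0 = min(max(anchor_rank - offset, 0), n_per - size)
        else:
            ci_a = int(rng.integers(0, n_chrom))
            a0 = int(rng.integers(0, n_per - size + 1))
        ci_b = int(rng.integers(0, n_chrom - 1))
        if ci_b >= ci_a:
            ci_b += 1
        b0 = int(rng.integers(0, n_per - size + 1))
        block_id = f"{bi}"
        for i in range(size):
            above = bool(rng.random() < config.fraction_ks_above_threshold)
            ks = _sample_ks(rng, config, above)
            pairs.append(
                CollinearPair(
                    block_id=f"block_{block_id}",
                    gene_a=_gene_id(ci_a + 1, a0 + i),
                    gene_b=_gene_id(ci_b + 1, b0 + i),
                    ks=ks,
                )
            )
    # A couple of scaffold lectins may still duplicate segmentally: pair
    # each with a random placed gene through a dedicated block.
    for ui, (scaf, _s, _e, _strand, gid) in enumerate(scaffold_rows):
        if config.n_collinear_blocks > 0 and rng.random() < 0.5:
            ci = int(rng.integers(0, n_chrom))
            r = int(rng.integers(0, n_per))
            above = bool(rng.random() < config.fraction_ks_above_threshold)
            pairs.append(
                CollinearPair(
                    block_id=f"block_u{ui}",
                    gene_a=gid,
                    gene_b=_gene_id(ci + 1, r),
                    ks=_sample_ks(rng, config, above),
                )
            )

    # --- mechanism truth --------------------------------------------------
    tandem_genes = {g for c in clusters for g in c.members}
    lectins = set(family_by_gene)
    segmental_genes: set[str] = set()
    for p in pairs:
        if p.ks is not None and p.ks <= config.ks_threshold:
            segmental_genes.update({p.gene_a, p.gene_b} & lectins)
    mechanism_by_gene = {}
    for gid in lectins:
        in_t, in_s = gid in tandem_genes, gid in segmental_genes
        mechanism_by_gene[gid] = (
            "both" if (in_t and in_s)
            else "tandem_only" if in_t
            else "segmental_only" if in_s
            else "other"
        )

    # --- domain hits, topology, architectures ----------------------------
    domain_lines = [
        "protein_id\tdomain_accession\tdescription\td_start\td_end\tscore_or_evalue"
    ]
    topo_lines = ["protein_id\thas_signal_peptide\ttm_segments"]
    architecture_by_gene: dict[str, str] = {}

    def emit_protein(gid: str, family: str | None) -> None:
        if family is None:
            # background gene: occasionally a non-lectin domain and
            # noisy SP/TM calls
            has_sp = bool(rng.random() < config.signal_peptide_rate * 0.2)
            segs = []
            if rng.random() < config.tm_rate * 0.3:
                s = int(rng.integers(5, 400))
                segs.append((s, s + 20))
            if rng.random() < 0.2:
                start = int(rng.integers(1, 200))
                domain_lines.append(
                    f"{gid}\tDOM_KINASE\tProtein kinase domain\t{start}\t"
                    f"{start + 279}\t{10.0 ** -float(rng.integers(10, 60)):.1e}"
                )
            topo_lines.append(
                f"{gid}\t{str(has_sp).lower()}\t"
                + ";".join(f"{a}-{b}" for a, b in segs)
            )
            return

        templates = ARCHITECTURE_TEMPLATES[family]
        weights = np.array([w for w, _t in templates])
        weights = weights / weights.sum()
        tokens = templates[int(rng.choice(len(templates), p=weights))][1]
        cursor = 1
        has_sp = False
        segs = []
        arch_tokens = []
        for tok in tokens:
            if tok == "SP":
                has_sp = True
                cursor += 25
                arch_tokens.append("SP")
                continue
            if tok == "TM":
                segs.append((cursor, cursor + 20))
                cursor += 21 + int(rng.integers(3, 15))
                arch_tokens.append("TM")
                continue
            acc, length = TOKEN_ACCESSIONS[tok]
            d_start = cursor + int(rng.integers(3, 20))
            d_end = d_start + length - 1
            evalue = 10.0 ** -float(rng.integers(15, 80))
            desc = tok.replace("*", "") + " domain"
            domain_lines.append(
                f"{gid}\t{acc}\t{desc}\t{d_start}\t{d_end}\t{evalue:.1e}"
            )
            cursor = d_end + 1
            arch_tokens.append(tok.replace("GNA*", "GNA"))
        topo_lines.append(
            f"{gid}\t{str(has_sp).lower()}\t"
            + ";".join(f"{a}-{b}" for a, b in segs)
        )
        architecture_by_gene[gid] = "|".join(
            t.replace("GNA*", "GNA") for t in arch_tokens
        )

    gff_lines = ["##gff-version 3"]
    for ci in range(n_chrom):
        for gi in range(n_per):
            gid = _gene_id(ci + 1, gi)
            gff_lines.append(
                f"{chrom_names[ci]}\tlectinscape_sim\tgene\t{starts[ci, gi]}\t"
                f"{ends[ci, gi]}\t.\t{strands[ci][gi]}\t.\tID={gid}"
            )
            fam = placed.get((ci, gi), (None, None))[0]
            emit_protein(gid, fam)
    for scaf, s, e, strand, gid in scaffold_rows:
        gff_lines.append(
            f"{scaf}\tlectinscape_sim\tgene\t{s}\t{e}\t.\t{strand}\t.\tID={gid}"
        )
        emit_protein(gid, family_by_gene[gid])

    # --- collinearity text -------------------------------------------------
    coll_lines = ["## MCScanX-style collinearity (synthetic)"]
    current_block = None
    idx_in_block = 0
    for p in pairs:
        if p.block_id != current_block:
            current_block = p.block_id
            idx_in_block = 0
            token = p.block_id.replace("block_", "")
            coll_lines.append(
                f"## Alignment {token}: score=0 e_value=0 N=0 synthetic plus"
            )
        ks_text = "NA" if p.ks is None else f"{p.ks:.4f}"
        coll_lines.append(
            f"{token}-{idx_in_block}:\t{p.gene_a}\t{p.gene_b}\t{ks_text}"
        )
        idx_in_block += 1

    truth = TruthLabels(
        family_by_gene=family_by_gene,
        mechanism_by_gene=mechanism_by_gene,
        clusters=clusters,
        collinear_pairs=pairs,
        architecture_by_gene=architecture_by_gene,
    )
    return SimulatedGenome(
        gff3="\n".join(gff_lines) + "\n",
        domain_tsv="\n".join(domain_lines) + "\n",
        topology_tsv="\n".join(topo_lines) + "\n",
        collinearity_txt="\n".join(coll_lines) + "\n",
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Printed-table fixtures (the survey's worked inputs)
# ---------------------------------------------------------------------------


def table1_fixture() -> dict[str, int]:
    """Per-family predicted gene counts of the published survey:
    nine nonzero families and three families without soybean homologs."""
    return {
        "ABA": 0,
        "amaranthin": 0,
        "CRA": 6,
        "cyanovirin": 0,
        "EUL": 3,
        "GNA": 166,
        "hevein": 6,
        "jacalin": 5,
        "legume": 94,
        "LysM": 47,
        "Nictaba": 22,
        "ricin B": 10,
    }


def table3_fixture() -> dict[str, tuple[int, int, int]]:
    """Per-family (tandem clusters, tandem genes, segmental genes) as
    printed in the survey's duplication table."""
    return {
        "CRA": (0, 0, 4),
        "EUL": (1, 2, 0),
        "GNA": (26, 114, 69),
        "hevein": (1, 2, 3),
        "jacalin": (0, 0, 5),
        "legume": (16, 49, 51),
        "LysM": (2, 4, 38),
        "Nictaba": (5, 13, 11),
        "ricin B": (2, 4, 7),
    }
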