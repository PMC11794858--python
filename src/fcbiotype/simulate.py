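"""Synthetic cohort generator for the biotyping pipeline.

Emulates the statistical structure the analysis assumes: a CHR group of
151 subjects carrying three latent biotypes (29.8% / 19.2% / 51.0%) with
network-specific signed shifts of Fisher-z connectivity, 88 matched
healthy controls, clinical items linearly coupled to a subset of the
affected edges, and a battery of parcellated neurotransmitter maps of
which a few are spatially correlated with each biotype's abnormality
profile.

All randomness flows through seed-spawned substreams (connectome,
clinical, demographics, maps), so e.g. adding maps never perturbs the
connectome draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import Atlas, default_atlas
from .cohort import CLINICAL_ITEMS, GAF_SCORES, MCCB_TESTS, SIPS_ITEMS, CohortTable
from .connectome import ConnectomeStack, devectorize, edge_index
from .errors import DesignError
from .maps import MapTable

#: (biotype, network_a, network_b, sign, delta) — signed Fisher-z shifts
#: applied to every edge of the network-pair block for subjects of that
#: biotype.  Biotype 1: strengthened somatomotor coupling with weakened
#: visual-subcortical links.  Biotype 2: subcortical (thalamo-striatal)
#: hyperconnectivity plus visual/dorsal-attention/somatomotor increases,
#: with reduced within-visual and somatomotor-subcortical coupling.
#: Biotype 3: diffuse reductions sparing visual and dorsal-attention,
#: with increased limbic-subcortical and limbic-somatomotor coupling.
DEFAULT_EFFECTS = (
    (1, "somatomotor", "somatomotor", +1, 0.30),
    (1, "visual", "subcortical", -1, 0.26),
    (2, "subcortical", "subcortical", +1, 0.30),
    (2, "visual", "dorsal_attention", +1, 0.23),
    (2, "visual", "somatomotor", +1, 0.23),
    (2, "dorsal_attention", "somatomotor", +1, 0.23),
    (2, "visual", "visual", -1, 0.26),
    (2, "somatomotor", "subcortical", -1, 0.26),
    (3, "limbic", "subcortical", +1, 0.29),
    (3, "limbic", "somatomotor", +1, 0.26),
    (3, "default", "default", -1, 0.23),
    (3, "default", "frontoparietal", -1, 0.20),
    (3, "somatomotor", "somatomotor", -1, 0.23),
    (3, "subcortical", "subcortical", -1, 0.23),
    (3, "ventral_attention", "default", -1, 0.20),
    (3, "frontoparietal", "subcortical", -1, 0.20),
    (3, "subcortical", "somatomotor", -1, 0.23),
)

#: 39 receptor/transporter map names (PET/SPECT tracer families).
MAP_NAMES = (
    "5HT1a", "5HT1b", "5HT2a", "5HT4", "5HT6", "5HTT",
    "A4B2", "CB1", "D1", "D2", "DAT", "GABAa", "H3", "M1",
    "mGluR5", "MOR", "KOR", "NET", "NMDA", "VAChT",
    "5HT1a_cumi", "5HT1b_p943", "5HT2a_cimbi", "5HTT_dasb",
    "D2_flb457", "D2_fallypride", "DAT_fepe2i", "GABAa_fmz",
    "CB1_omar", "MOR_carfentanil", "NET_mrb", "NMDA_ge179",
    "mGluR5_abp688", "VAChT_feobv", "A4B2_flubatine", "M1_lsn3172176",
    "H3_gsk189254", "5HT4_sb207145", "5HT6_gsk215083",
)
#: Maps carrying planted spatial correlation with the biotype profiles,
#: one per biotype (serotonergic / dopaminergic / opioid families).
COUPLED_MAPS = {"5HTT": 1, "D2": 2, "MOR": 3}


@dataclass
class SimulationDesign:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 151 CHR + 88 HC, a
    246-region atlas, biotype proportions 0.298/0.192/0.510, signed
    block effects of 0.15-0.25 Fisher-z units, 600 symptom-coupled
    edges at target |r| = 0.4, and 39 maps with one map per biotype
    planted at spatial correlation 0.6.
    """

    n_chr: int = 151
    n_hc: int = 88
    atlas: Atlas | None = None
    biotype_proportions: tuple = (0.298, 0.192, 0.510)
    effect_map: tuple = DEFAULT_EFFECTS
    effect_scale: float = 1.0
    n_coupled_edges: int = 600
    coupling_strength: float = 0.4
    symptom_loading: float = 0.12
    item_noise_sd: float = 0.15
    within_mean: float = 0.45
    between_mean: float = 0.10
    edge_mean_sd: float = 0.10
    noise_sd: float = 0.15
    n_maps: int = 39
    map_rho: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.atlas is None:
            self.atlas = default_atlas()
        props = np.asarray(self.biotype_proportions, dtype=float)
        if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
            raise DesignError(
                f"biotype proportions must be nonnegative and sum to 1, got {props}"
            )
        if not np.all(np.isfinite([d for *_, d in self.effect_map])):
            raise DesignError("effect sizes must be finite")
        if abs(self.coupling_strength) >= 1:
            raise DesignError(
                f"coupling target |r| = {self.coupling_strength} is infeasible (>= 1)"
            )
        if abs(self.map_rho) > 1:
            raise DesignError(f"|map_rho| = {abs(self.map_rho)} > 1 is infeasible")
        if self.n_maps < len(COUPLED_MAPS):
            raise DesignError(f"need at least {len(COUPLED_MAPS)} maps")

    @property
    def P(self) -> int:
        return self.atlas.P

    def biotype_counts(self) -> np.ndarray:
        """Integer biotype sizes by largest-remainder apportionment."""
        props = np.asarray(self.biotype_proportions, dtype=float)
        raw = props * self.n_chr
        counts = np.floor(raw).astype(int)
        short = self.n_chr - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
        return counts


@dataclass
class GroundTruth:
    """Planted structure, for recovery tests and benchmarking."""

    biotype_labels: np.ndarray          # per CHR subject, 1..3
    coupled_edge_ids: np.ndarray        # selection targets
    delta: np.ndarray                   # 3 x n_edges signed planted shifts
    node_profiles: np.ndarray           # 3 x P signed abnormality profiles
    coupled_edge_domains: np.ndarray | None = None  # 0..3 per coupled edge
    map_true_rho: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "biotype_labels": self.biotype_labels.tolist(),
            "coupled_edge_ids": self.coupled_edge_ids.tolist(),
            "coupled_edge_domains": (
                self.coupled_edge_domains.tolist()
                if self.coupled_edge_domains is not None
                else None
            ),
            "node_profiles": self.node_profiles.tolist(),
            "map_true_rho": self.map_true_rho,
        }


def _block_edge_ids(atlas: Atlas, net_a: str, net_b: str) -> np.ndarray:
    """Edge ids whose endpoints lie in the (net_a, net_b) network pair."""
    na, nb = atlas.edge_networks()
    mask = ((na == net_a) & (nb == net_b)) | ((na == net_b) & (nb == net_a))
    return np.flatnonzero(mask)


def planted_delta(design: SimulationDesign) -> np.ndarray:
    """3 x n_edges matrix of signed Fisher-z shifts per biotype."""
    atlas = design.atlas
    delta = np.zeros((3, atlas.n_edges))
    for biotype, net_a, net_b, sign, d in design.effect_map:
        ids = _block_edge_ids(atlas, net_a, net_b)
        delta[biotype - 1, ids] += sign * d * design.effect_scale
    return delta


def _node_profiles(design: SimulationDesign, delta: np.ndarray) -> np.ndarray:
    """Signed true abnormality profile per biotype: per-ROI count of
    increased minus decreased edges, mirroring the degree-based scoring
    applied to thresholded contrast maps."""
    P = design.P
    iu, ju = edge_index(P)
    profiles = np.zeros((3, P))
    for b in range(3):
        pos = delta[b] > 0
        neg = delta[b] < 0
        profiles[b] = (
            np.bincount(iu[pos], minlength=P) + np.bincount(ju[pos], minlength=P)
            - np.bincount(iu[neg], minlength=P) - np.bincount(ju[neg], minlength=P)
        )
    return profiles


def simulate_cohort(design: SimulationDesign):
    """Draw one synthetic cohort.

    Returns
    -------
    cohort : CohortTable
    stack : ConnectomeStack
        Fisher-z edge table, HC then CHR subject blocks interleaved by id.
    truth : GroundTruth
    """
    atlas = design.atlas
    E = atlas.n_edges
    ss = np.random.SeedSequence(design.seed)
    rng_conn, rng_clin, rng_demo, _rng_maps = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # --- connectomes ---------------------------------------------------
    na, nb = atlas.edge_networks()
    within = na == nb
    mu0 = np.where(within, design.within_mean, design.between_mean)
    mu0 = mu0 + rng_conn.normal(0.0, design.edge_mean_sd, size=E)

    counts = design.biotype_counts()
    labels = np.repeat(np.arange(1, 4), counts)
    rng_conn.shuffle(labels)

    delta = planted_delta(design)
    n_total = design.n_chr + design.n_hc
    edges = np.empty((n_total, E))
    # HC block first, then CHR
    edges[: design.n_hc] = mu0 + rng_conn.normal(
        0.0, design.noise_sd, size=(design.n_hc, E)
    )
    edges[design.n_hc:] = (
        mu0
        + delta[labels - 1]
        + rng_conn.normal(0.0, design.noise_sd, size=(design.n_chr, E))
    )
    subject_ids = [f"HC{i + 1:03d}" for i in range(design.n_hc)] + [
        f"CHR{i + 1:03d}" for i in range(design.n_chr)
    ]
    stack = ConnectomeStack(subject_ids, edges, P=atlas.P)

    # --- coupled edges and clinical items ------------------------------
    # Symptom severity is modeled as four subject-level latent axes (one
    # per SIPS domain), each loading on its own share of the
    # biotype-affected edges in the planted direction, orthogonal to
    # biotype membership.  Coupled edges then carry the designed item
    # correlation with the items of their domain while uncoupled edges
    # stay null, so the selection screen has a well-defined target set;
    # spreading severity over four axes keeps the within-biotype
    # geometry close to isotropic.
    affected = np.flatnonzero(np.abs(delta).sum(axis=0) > 0)
    pool = affected if affected.size else np.arange(E)
    n_cpl = min(design.n_coupled_edges, pool.size)
    coupled = np.sort(rng_clin.choice(pool, size=n_cpl, replace=False))

    domains = ("positive", "negative", "disorganization", "general")
    item_domain = {}
    for name in SIPS_ITEMS:
        item_domain[name] = {"P": 0, "N": 1, "D": 2, "G": 3}[name[0]]
    edge_domain = rng_clin.integers(0, 4, size=n_cpl)

    align = np.sign(delta.sum(axis=0))[coupled]
    align[align == 0] = 1.0
    severity = rng_conn.standard_normal((design.n_chr, 4))
    if design.symptom_loading != 0 and n_cpl:
        edges[design.n_hc:, coupled] += (
            design.symptom_loading * severity[:, edge_domain] * align[None, :]
        )
    chr_edges = edges[design.n_hc:]
    zc = chr_edges[:, coupled] * align
    # remove the between-biotype component so items track severity, not
    # biotype membership
    zc_centered = zc.copy()
    for b in (1, 2, 3):
        m = labels == b
        if m.any():
            zc_centered[m] -= zc_centered[m].mean(axis=0)

    def _latent(edge_mask):
        """Calibrated item latent from a random half of the masked edges."""
        ids = np.flatnonzero(edge_mask)
        sub = ids[rng_clin.random(ids.size) < 0.5]
        if sub.size == 0 and ids.size:
            sub = ids[[rng_clin.integers(ids.size)]]
        u = zc_centered[:, sub].mean(axis=1)
        u = (u - u.mean()) / u.std()
        # calibrate the mixing weight so the mean |r| between the item
        # and its coupled edges hits the design target
        ze = zc[:, sub]
        zs = (ze - ze.mean(0)) / ze.std(0)
        c_mean = np.abs(zs.T @ u).mean() / design.n_chr
        rho = min(target / max(c_mean, 1e-12), 0.99)
        return rho * u + np.sqrt(1 - rho**2) * rng_clin.standard_normal(design.n_chr)

    items = {}
    target = abs(design.coupling_strength)
    for name in SIPS_ITEMS:
        if target > 0 and n_cpl:
            items[name] = _latent(edge_domain == item_domain[name])
        else:
            items[name] = rng_clin.standard_normal(design.n_chr)
    for name in GAF_SCORES:
        # functioning reflects overall severity: couple to all domains
        if target > 0 and n_cpl:
            items[name] = _latent(np.ones(n_cpl, dtype=bool))
        else:
            items[name] = rng_clin.standard_normal(design.n_chr)

    # map standardized severities onto plausible clinical scales; GAF
    # decreases with severity
    clin = pd.DataFrame(index=range(n_total), columns=list(CLINICAL_ITEMS), dtype=float)
    for name in SIPS_ITEMS:
        chr_vals = 2.0 + 1.0 * items[name]
        hc_vals = rng_clin.normal(0.1, design.item_noise_sd, size=design.n_hc)
        clin.loc[: design.n_hc - 1, name] = np.abs(hc_vals)
        clin.loc[design.n_hc:, name] = chr_vals
    gaf_scale = {"gaf_before": (78.3, 7.4, 80.7, 1.9), "gaf_now": (56.8, 7.8, 80.3, 2.2)}
    for name in GAF_SCORES:
        m_chr, s_chr, m_hc, s_hc = gaf_scale[name]
        clin.loc[: design.n_hc - 1, name] = rng_clin.normal(m_hc, s_hc, design.n_hc)
        clin.loc[design.n_hc:, name] = m_chr - s_chr * items[name]

    # --- demographics and cognition ------------------------------------
    demo = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": ["HC"] * design.n_hc + ["CHR"] * design.n_chr,
            "age": rng_demo.normal(19.0, 5.0, n_total).clip(13, 45),
            "sex": np.where(rng_demo.random(n_total) < 0.5, "F", "M"),
            "education": rng_demo.normal(11.3, 2.5, n_total).clip(6, None),
        }
    )
    # MCCB: CHR impaired relative to HC, magnitudes in line with published
    # CHR-vs-control cognitive batteries
    mccb_scale = {
        "TMT": (33.9, 16.3, 28.2, 8.6),
        "BACS_SC": (56.8, 10.5, 66.2, 9.5),
        "HVLT_R": (23.0, 4.8, 26.3, 3.6),
        "WMS_III_SS": (16.0, 3.2, 17.4, 3.0),
        "NAB_Mazes": (16.8, 6.6, 19.5, 4.9),
        "BVMT_R": (26.4, 6.5, 29.9, 4.7),
        "Fluency": (19.4, 4.9, 23.1, 5.0),
        "CPT_IP": (2.4, 0.76, 2.6, 0.70),
    }
    for name in MCCB_TESTS:
        m_chr, s_chr, m_hc, s_hc = mccb_scale[name]
        vals = np.empty(n_total)
        vals[: design.n_hc] = rng_demo.normal(m_hc, s_hc, design.n_hc)
        vals[design.n_hc:] = rng_demo.normal(m_chr, s_chr, design.n_chr)
        demo[name] = vals

    table = pd.concat([demo, clin], axis=1)
    table["sips_positive"] = table[["P1", "P2", "P3", "P4", "P5"]].sum(axis=1)
    table["sips_negative"] = table[["N1", "N2", "N3", "N4", "N5", "N6"]].sum(axis=1)
    table["sips_disorganization"] = table[["D1", "D2", "D3", "D4"]].sum(axis=1)
    table["sips_general"] = table[["G1", "G2", "G3", "G4"]].sum(axis=1)
    cohort = CohortTable(table)

    truth = GroundTruth(
        biotype_labels=labels,
        coupled_edge_ids=coupled,
        delta=delta,
        node_profiles=_node_profiles(design, delta),
        coupled_edge_domains=edge_domain,
    )
    return cohort, stack, truth


def simulate_maps(design: SimulationDesign, truth: GroundTruth) -> MapTable:
    """Draw the neurotransmitter map battery.

    Coupled maps are ``rho * standardized(profile) + sqrt(1-rho^2) * noise``
    so the planted spatial correlation equals ``design.map_rho`` in
    expectation; the remaining maps are independent spatial noise.
    Uses its own RNG substream: map draws never perturb the cohort.
    """
    P = design.P
    ss = np.random.SeedSequence(design.seed)
    rng = np.random.default_rng(ss.spawn(4)[3])
    names = list(MAP_NAMES[: design.n_maps])
    rho = design.map_rho
    values = {}
    true_rho = {}
    for name in names:
        noise = rng.standard_normal(P)
        if name in COUPLED_MAPS and rho != 0:
            b = COUPLED_MAPS[name] - 1
            prof = truth.node_profiles[b]
            prof = (prof - prof.mean()) / prof.std()
            noise = (noise - noise.mean()) / noise.std()
            vec = rho * prof + np.sqrt(1 - rho**2) * noise
            true_rho[name] = {"biotype": b + 1, "rho": float(rho)}
        else:
            vec = noise
            true_rho[name] = {"biotype": None, "rho": 0.0}
        values[name] = vec
    truth.map_true_rho = true_rho
    metadata = {
        n: {"tracer": n, "source": "synthetic", "coupled_biotype": true_rho[n]["biotype"]}
        for n in names
    }
    return MapTable(pd.DataFrame(values), metadata)


def planted_truth(design: SimulationDesign) -> GroundTruth:
    """Deterministic part of the ground truth (no cohort draw needed):
    the planted delta matrix and the signed node profiles.  Labels and
    coupled edges are left empty; use :func:`simulate_cohort` for a
    full draw."""
    delta = planted_delta(design)
    return GroundTruth(
        biotype_labels=np.array([], dtype=int),
        coupled_edge_ids=np.array([], dtype=int),
        delta=delta,
        node_profiles=_node_profiles(design, delta),
    )


def null_design(seed: int = 0, **overrides) -> SimulationDesign:
    """Design with no planted structure: delta = 0 everywhere, no
    symptom coupling.  CHR and HC edge distributions are then identical
    in expectation — the null for calibration checks."""
    kw = dict(effect_scale=0.0, coupling_strength=0.0, symptom_loading=0.0, seed=seed)
    kw.update(overrides)
    return SimulationDesign(**kw)


def planted_threshold_maps(design: SimulationDesign, truth: GroundTruth):
    """True signed binary P x P effect masks per biotype (for tests)."""
    masks = []
    for b in range(3):
        pos = devectorize((truth.delta[b] > 0).astype(np.uint8), design.P)
        neg = devectorize((truth.delta[b] < 0).astype(np.uint8), design.P)
        masks.append((pos, neg))
    return masks
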