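"""Synthetic paired tumor/normal H3K27ac cohort with planted structure.

The generator emulates a cohort at the stage the pipeline consumes:
normalized log2 peak signal (counts are never simulated), a log-scale
gene-by-tumor-sample expression matrix, sample metadata and a TSS table.
Every downstream statistical assumption has a planted counterpart:

* tumor-vs-normal differential peaks (mean shift in one tissue);
* tumor-only hyper-variable peaks carrying a two-subgroup split (GI/GII)
  that agrees with a clinical covariate in ~85% of patients;
* runs of closely spaced, high-signal peaks forming super-enhancers;
* distal enhancer-gene pairs sharing a latent factor so their expected
  Pearson correlation equals ``link_rho``;
* regulator genes that are subgroup-DEGs, planted regulator→target edges,
  and one highly inter-correlated core-regulator clique per subgroup.

One chromosome is always named ``chrX`` to exercise the sex-chromosome
filter.  The ``seed`` fully determines the output.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .intervals import sort_intervals


class ConfigError(ValueError):
    """A SyntheticConfig invariant is violated."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Effect sizes are on the log2 signal scale.  Defaults describe the
    standard desk-scale cohort: 40 patients (80 ChIP samples), 2,000
    consensus peaks of which 100 are hyper-variable with a full
    between-subgroup shift of 2 (i.e. a 4-fold signal ratio), ten planted
    super-enhancer clusters and 50 true enhancer-gene links at rho = 0.8.
    """

    n_patients: int = 40
    n_chromosomes: int = 4          # chr1..chr{n-1} plus chrX
    chrom_length: int = 60_000_000  # bp
    n_peaks: int = 2000
    frac_tumor_specific: float = 0.10
    frac_normal_specific: float = 0.10
    diff_effect: float = 2.0        # log2 shift of tissue-specific peaks
    n_hvp: int = 100
    subgroup_split: float = 0.5     # fraction of patients in group II
    hvp_effect: float = 2.0         # log2 shift between planted subgroups
    n_se_clusters: int = 10
    peaks_per_se: int = 5
    se_within_gap: int = 3000       # bp, must stay < the 12.5-kb stitch gap
    se_boost: float = 2.5           # log2 elevation of SE member peaks
    n_genes: int = 500
    n_true_links: int = 50
    link_rho: float = 0.8
    n_regulators: int = 30
    core_clique_size: int = 6       # per subgroup
    core_clique_rho: float = 0.9
    n_deg: int = 200                # subgroup-specific expressed genes
    deg_effect: float = 2.5
    n_bipartite_regulators: int = 5
    targets_per_regulator: int = 4
    target_rho: float = 0.8
    covariate_agreement: float = 0.85
    noise_sd: float = 0.3
    expr_noise_sd: float = 0.5
    seed: int = 0
    layout_seed: int | None = None  # share genome/gene roles across cohorts

    def validate(self) -> "SyntheticConfig":
        for name in ("frac_tumor_specific", "frac_normal_specific",
                     "subgroup_split", "link_rho", "core_clique_rho",
                     "target_rho", "covariate_agreement"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.se_within_gap >= 12_500:
            raise ConfigError(
                f"se_within_gap={self.se_within_gap} must be < 12500 (stitch gap)"
            )
        for name in ("n_patients", "n_chromosomes", "chrom_length", "n_peaks",
                     "n_genes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("n_hvp", "n_se_clusters", "peaks_per_se", "n_true_links",
                     "n_regulators", "core_clique_size", "n_deg"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.noise_sd < 0 or self.expr_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        n_structured = (self.n_se_clusters * self.peaks_per_se + self.n_hvp
                        + self.n_true_links)
        if n_structured > self.n_peaks:
            raise ConfigError(
                f"planted structure needs {n_structured} peaks but n_peaks="
                f"{self.n_peaks}"
            )
        if 2 * self.core_clique_size + self.n_bipartite_regulators > self.n_regulators:
            raise ConfigError("core cliques and hub regulators exceed n_regulators")
        n_planted_genes = (self.n_regulators + self.n_deg + self.n_true_links
                          + self.n_bipartite_regulators * self.targets_per_regulator)
        if n_planted_genes > self.n_genes:
            raise ConfigError("planted gene structure exceeds n_genes")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    subgroup: dict[str, str]              # tumor sample id -> GI / GII
    tumor_specific: list[str]             # peak ids
    normal_specific: list[str]
    hvp: list[str]
    se_regions: pd.DataFrame              # chrom/start/end/members
    links: list[tuple[str, str]]          # (enhancer peak id, gene id)
    regulators: list[str]
    bipartite_edges: list[tuple[str, str]]
    core_clique: dict[str, list[str]]     # subgroup -> members
    gi_genes: list[str]
    gii_genes: list[str]


@dataclass
class Cohort:
    """In-memory synthetic cohort: all inputs the pipeline stages consume."""

    config: SyntheticConfig
    peaks: pd.DataFrame                   # chrom/start/end/peak_id
    signal: pd.DataFrame                  # peak x (tumor+normal) log2 signal
    expression: pd.DataFrame              # gene x tumor-sample log expression
    samples: pd.DataFrame                 # sample_id/patient_id/tissue/covariates
    tss: pd.DataFrame                     # gene_id/chrom/tss/strand
    truth: SyntheticTruth


def _latent_loading(rho: float, sd: float) -> float:
    """Loading a on a N(0,1) factor so that corr(a*z+e1, a*z+e2) = rho."""
    if rho >= 1.0:
        return np.inf
    return sd * np.sqrt(rho / (1.0 - rho))


def generate_cohort(config: SyntheticConfig) -> Cohort:
    cfg = config.validate()
    # layout stream: genome geometry and planted roles (shared between
    # cohorts that set the same layout_seed); sample stream: patients,
    # noise and latent factors
    layout_seed = cfg.seed if cfg.layout_seed is None else cfg.layout_seed
    layout = np.random.default_rng(layout_seed)
    rng = np.random.default_rng([cfg.seed, 7141])
    chroms = [f"chr{i}" for i in range(1, cfg.n_chromosomes)] + ["chrX"]

    # ---- samples & covariates -------------------------------------------
    patients = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    tumor_ids = [f"{p}_T" for p in patients]
    normal_ids = [f"{p}_N" for p in patients]
    n_gii = int(round(cfg.subgroup_split * cfg.n_patients))
    gii_idx = rng.choice(cfg.n_patients, size=n_gii, replace=False)
    subgroup = np.array(["GI"] * cfg.n_patients, dtype=object)
    subgroup[gii_idx] = "GII"

    agree = rng.random(cfg.n_patients) < cfg.covariate_agreement
    node_status = np.where(
        agree == (subgroup == "GII"), "positive", "negative"
    )
    gender = rng.choice(["male", "female"], size=cfg.n_patients)
    smoking = rng.choice(["ever", "never"], size=cfg.n_patients)
    samples = pd.DataFrame(
        {
            "sample_id": tumor_ids + normal_ids,
            "patient_id": patients + patients,
            "tissue": ["tumor"] * cfg.n_patients + ["normal"] * cfg.n_patients,
            "node_status": list(node_status) * 2,
            "gender": list(gender) * 2,
            "smoking": list(smoking) * 2,
        }
    )

    # ---- genes / TSS -----------------------------------------------------
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    gene_chrom_idx = layout.integers(0, len(chroms), size=cfg.n_genes)
    margin = 600_000 if cfg.chrom_length > 1_300_000 else cfg.chrom_length // 10
    tss_pos = layout.integers(margin, cfg.chrom_length - margin, size=cfg.n_genes)
    tss = pd.DataFrame(
        {
            "gene_id": genes,
            "chrom": [chroms[i] for i in gene_chrom_idx],
            "tss": tss_pos,
            "strand": layout.choice(["+", "-"], size=cfg.n_genes),
        }
    )
    tss = tss.sort_values(["chrom", "tss"], kind="mergesort").reset_index(drop=True)
    genes = list(tss["gene_id"])

    # ---- peak placement --------------------------------------------------
    # SE clusters: tight runs of peaks_per_se peaks on autosomes, anchored
    # far from every TSS so the 2.5-kb exclusion never trims them.
    peak_rows: list[tuple[str, int, int, str]] = []  # chrom,start,end,kind
    tss_by_chrom = {
        c: np.sort(sub["tss"].to_numpy()) for c, sub in tss.groupby("chrom")
    }

    def far_from_tss(chrom: str, lo: int, hi: int, pad: int = 5000) -> bool:
        arr = tss_by_chrom.get(chrom)
        if arr is None or len(arr) == 0:
            return True
        j = np.searchsorted(arr, lo - pad)
        return not (j < len(arr) and arr[j] <= hi + pad)

    autosomes = chroms[:-1] if len(chroms) > 1 else chroms
    width_se = 800
    cluster_span = cfg.peaks_per_se * width_se + (cfg.peaks_per_se) * cfg.se_within_gap
    placed = 0
    attempts = 0
    se_clusters: list[list[tuple[str, int, int]]] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    while placed < cfg.n_se_clusters and attempts < 10000:
        attempts += 1
        chrom = autosomes[placed % len(autosomes)]
        anchor = int(layout.integers(10_000, cfg.chrom_length - cluster_span - 10_000))
        if not far_from_tss(chrom, anchor, anchor + cluster_span):
            continue
        if any(lo < anchor + cluster_span + 20_000 and anchor - 20_000 < hi
               for lo, hi in occupied[chrom]):
            continue
        pos = anchor
        members = []
        for _ in range(cfg.peaks_per_se):
            gap = int(layout.integers(200, max(201, cfg.se_within_gap)))
            members.append((chrom, pos, pos + width_se))
            pos += width_se + gap
        se_clusters.append(members)
        occupied[chrom].append((anchor, pos))
        placed += 1
    if placed < cfg.n_se_clusters:
        raise ConfigError("could not place SE clusters; enlarge chrom_length")

    for members in se_clusters:
        for chrom, lo, hi in members:
            peak_rows.append((chrom, lo, hi, "se"))

    # background peaks: random distal positions (>= 5 kb from any TSS),
    # kept >= 500 bp apart from everything already placed on the chromosome
    import bisect

    n_background = cfg.n_peaks - len(peak_rows)
    per_chrom = np.bincount(
        layout.integers(0, len(chroms), size=n_background), minlength=len(chroms)
    )
    for ci, chrom in enumerate(chroms):
        need = int(per_chrom[ci])
        occ = sorted(occupied[chrom])  # (start, end) of blocked spans
        occ_starts = [x[0] for x in occ]
        occ_ends = [x[1] for x in occ]
        got = 0
        tries = 0
        while got < need:
            tries += 1
            if tries > need * 200 + 10_000:
                raise ConfigError(
                    "could not place background peaks; enlarge chrom_length"
                )
            w = int(layout.integers(400, 1200))
            s = int(layout.integers(1000, cfg.chrom_length - w - 1000))
            if not far_from_tss(chrom, s, s + w):
                continue
            j = bisect.bisect_right(occ_starts, s)
            if j > 0 and occ_ends[j - 1] > s - 500:
                continue
            if j < len(occ_starts) and occ_starts[j] < s + w + 500:
                continue
            occ_starts.insert(j, s)
            occ_ends.insert(j, s + w)
            peak_rows.append((chrom, s, s + w, "bg"))
            got += 1

    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "kind"])
    peaks = sort_intervals(peaks)
    peaks["peak_id"] = [f"peak_{i + 1:05d}" for i in range(len(peaks))]

    pid = peaks["peak_id"].to_numpy()
    kind = peaks["kind"].to_numpy()
    is_autosome = ~peaks["chrom"].str.lower().isin(["chrx", "chry"]).to_numpy()
    se_member_ids = [
        tuple(pid[(peaks["chrom"] == m[0][0]) & peaks["start"].isin([x[1] for x in m])])
        for m in se_clusters
    ]

    # assign planted roles among distal autosomal background peaks
    pool = np.flatnonzero((kind == "bg") & is_autosome)
    pool = layout.permutation(pool)
    n_ts = int(round(cfg.frac_tumor_specific * cfg.n_peaks))
    n_ns = int(round(cfg.frac_normal_specific * cfg.n_peaks))
    needed = cfg.n_hvp + cfg.n_true_links + n_ts + n_ns
    if needed > len(pool):
        raise ConfigError(
            f"not enough distal autosomal peaks ({len(pool)}) for planted "
            f"structure ({needed})"
        )
    hvp_idx = pool[: cfg.n_hvp]
    link_idx = pool[cfg.n_hvp: cfg.n_hvp + cfg.n_true_links]
    ts_idx = pool[cfg.n_hvp + cfg.n_true_links:
                  cfg.n_hvp + cfg.n_true_links + n_ts]
    ns_idx = pool[cfg.n_hvp + cfg.n_true_links + n_ts: needed]

    # ---- signal matrix ---------------------------------------------------
    n, p = cfg.n_patients, len(peaks)
    baseline = layout.normal(3.5, 0.8, size=p)
    baseline[kind == "se"] += cfg.se_boost
    sig = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(p, 2 * n))
    tumor_cols = np.arange(n)
    normal_cols = np.arange(n, 2 * n)
    sig[np.ix_(ts_idx, tumor_cols)] += cfg.diff_effect
    sig[np.ix_(ns_idx, normal_cols)] += cfg.diff_effect

    gii_mask = (subgroup == "GII")
    hvp_sign = layout.choice([-1.0, 1.0], size=cfg.n_hvp)
    shift = np.where(gii_mask, 0.5, -0.5)  # +/- hvp_effect/2 by subgroup
    sig[np.ix_(hvp_idx, tumor_cols)] += (
        cfg.hvp_effect * hvp_sign[:, None] * shift[None, :]
    )

    # ---- expression matrix (tumor samples) -------------------------------
    g = cfg.n_genes
    expr_base = layout.normal(5.0, 1.0, size=g)
    expr = expr_base[:, None] + rng.normal(0.0, cfg.expr_noise_sd, size=(g, n))
    gene_pos = {gene: i for i, gene in enumerate(genes)}

    # planted enhancer-gene links: pick for each link enhancer the nearest
    # eligible free gene within the 500-kb window
    gene_used = np.zeros(g, dtype=bool)
    links: list[tuple[str, str]] = []
    # The enhancer's total tumor variance is kept at noise_sd**2 by
    # splitting it between the shared factor (fraction link_rho) and
    # residual noise, so planted link enhancers are not hyper-variable.
    # The gene side keeps its full residual noise and takes an inflated
    # loading; the product of the two factor correlations is link_rho.
    lam_e = cfg.noise_sd * np.sqrt(cfg.link_rho)
    resid_e = cfg.noise_sd * np.sqrt(1.0 - cfg.link_rho)
    lam_g = _latent_loading(cfg.link_rho, cfg.expr_noise_sd)
    mid = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    reserved = set()  # genes reserved for regulator/DEG roles filled later
    for i in link_idx:
        chrom = peaks.at[i, "chrom"]
        cand = tss.index[(tss["chrom"] == chrom)
                         & (np.abs(tss["tss"] - mid[i]) <= 500_000)]
        cand = [j for j in cand if not gene_used[j]]
        if not cand:
            continue
        j = min(cand, key=lambda j: abs(int(tss.at[j, "tss"]) - int(mid[i])))
        gene_used[j] = True
        z = rng.normal(0.0, 1.0, size=n)
        sig[i, tumor_cols] = (
            baseline[i] + lam_e * z + rng.normal(0.0, resid_e, size=n)
        )
        expr[j, :] += lam_g * z
        links.append((pid[i], tss.at[j, "gene_id"]))
        reserved.add(tss.at[j, "gene_id"])

    # Regulators and subgroup DEGs carry a group mean shift in expression;
    # planted HVPs carry one in signal.  Keeping the two planted modules
    # more than a link window apart in the genome guarantees that no
    # un-planted (enhancer, gene) candidate pair is coupled through the
    # subgroup factor, so the link ground truth is unambiguous.
    hvp_mids = mid[hvp_idx]
    hvp_chroms = peaks["chrom"].to_numpy()[hvp_idx]
    gene_loc = dict(zip(tss["gene_id"], zip(tss["chrom"], tss["tss"])))

    def near_hvp(gene: str) -> bool:
        chrom, pos = gene_loc[gene]
        same = hvp_chroms == chrom
        return bool(
            same.any() and (np.abs(hvp_mids[same] - int(pos)) <= 510_000).any()
        )

    free = [gene for gene in genes if gene not in reserved]
    shifted_ok = [gene for gene in free if not near_hvp(gene)]
    layout.shuffle(free)
    layout.shuffle(shifted_ok)
    n_shifted = cfg.n_regulators + cfg.n_deg
    if len(shifted_ok) < n_shifted:
        raise ConfigError(
            f"only {len(shifted_ok)} genes lie outside the link windows of "
            f"planted HVPs but {n_shifted} subgroup-shifted genes are "
            "requested; enlarge chrom_length or reduce n_deg/n_regulators"
        )
    regulators = shifted_ok[: cfg.n_regulators]
    deg_genes = shifted_ok[cfg.n_regulators: n_shifted]
    taken = set(regulators) | set(deg_genes)
    rest = [gene for gene in free if gene not in taken]
    n_targets = cfg.n_bipartite_regulators * cfg.targets_per_regulator
    target_genes = rest[:n_targets]
    gi_core = regulators[: cfg.core_clique_size]
    gii_core = regulators[cfg.core_clique_size: 2 * cfg.core_clique_size]
    hub_regs = regulators[2 * cfg.core_clique_size:
                          2 * cfg.core_clique_size + cfg.n_bipartite_regulators]

    gshift = np.where(gii_mask, 0.5, -0.5)
    # every regulator is a subgroup DEG (direction: cores follow their group)
    for r in regulators:
        if r in gi_core:
            d = -cfg.deg_effect
        elif r in gii_core:
            d = cfg.deg_effect
        else:
            d = cfg.deg_effect * float(layout.choice([-1.0, 1.0]))
        expr[gene_pos[r], :] += d * gshift
    # ordinary subgroup DEGs, half up in each group
    gi_genes, gii_genes = [], []
    for idx, gene in enumerate(deg_genes):
        d = cfg.deg_effect if idx % 2 == 0 else -cfg.deg_effect
        expr[gene_pos[gene], :] += d * gshift
        (gii_genes if d > 0 else gi_genes).append(gene)
    gii_genes = sorted(gii_genes + list(gii_core))
    gi_genes = sorted(gi_genes + list(gi_core))

    def _group_orthogonal(z: np.ndarray) -> np.ndarray:
        # remove the factor's chance alignment with the subgroup split so
        # shared factors never distort planted fold changes
        z = z.copy()
        z[gii_mask] -= z[gii_mask].mean()
        z[~gii_mask] -= z[~gii_mask].mean()
        return z

    # core cliques: shared latent factor per subgroup with pairwise rho_c
    lam_c = _latent_loading(cfg.core_clique_rho, cfg.expr_noise_sd)
    for core in (gi_core, gii_core):
        z = _group_orthogonal(rng.normal(0.0, 1.0, size=n))
        for r in core:
            expr[gene_pos[r], :] += lam_c * z
    # bipartite hubs: each hub shares a factor with its planted targets
    lam_t = _latent_loading(cfg.target_rho, cfg.expr_noise_sd)
    bipartite_edges: list[tuple[str, str]] = []
    for hi, hub in enumerate(hub_regs):
        z = _group_orthogonal(rng.normal(0.0, 1.0, size=n))
        expr[gene_pos[hub], :] += lam_t * z
        for t in target_genes[hi * cfg.targets_per_regulator:
                              (hi + 1) * cfg.targets_per_regulator]:
            expr[gene_pos[t], :] += lam_t * z
            bipartite_edges.append((hub, t))

    truth = SyntheticTruth(
        subgroup={s: grp for s, grp in zip(tumor_ids, subgroup)},
        tumor_specific=sorted(pid[ts_idx]),
        normal_specific=sorted(pid[ns_idx]),
        hvp=sorted(pid[hvp_idx]),
        se_regions=pd.DataFrame(
            {
                "chrom": [m[0][0] for m in se_clusters],
                "start": [m[0][1] for m in se_clusters],
                "end": [m[-1][2] for m in se_clusters],
                "members": se_member_ids,
            }
        ).pipe(sort_intervals),
        links=sorted(links),
        regulators=sorted(regulators),
        bipartite_edges=sorted(bipartite_edges),
        core_clique={"GI": sorted(gi_core), "GII": sorted(gii_core)},
        gi_genes=gi_genes,
        gii_genes=gii_genes,
    )
    signal = pd.DataFrame(
        sig, index=pid, columns=tumor_ids + normal_ids
    ).rename_axis("peak_id")
    expression = pd.DataFrame(
        expr, index=genes, columns=tumor_ids
    ).rename_axis("gene_id")
    return Cohort(
        config=cfg,
        peaks=peaks[["chrom", "start", "end", "peak_id"]].copy(),
        signal=signal,
        expression=expression,
        samples=samples,
        tss=tss,
        truth=truth,
    )


# --------------------------------------------------------------------------
# fixtures on disk


def write_fixtures(cohort: Cohort, out_dir: str | Path) -> dict[str, str]:
    """Write the cohort as plain-text fixtures; returns the file manifest.

    Per-sample BED files carry the consensus peaks with that sample's
    signal as score; matrices/tables are TSV; planted truth is JSON.
    Re-reading with :func:`read_fixtures` reproduces the in-memory objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    bed_dir = out / "peaks"
    bed_dir.mkdir(exist_ok=True)
    for sample in cohort.signal.columns:
        df = cohort.peaks.copy()
        df["score"] = cohort.signal[sample].to_numpy()
        path = bed_dir / f"{sample}.bed"
        io.write_bed(df, path)
        manifest[f"bed:{sample}"] = str(path.relative_to(out))

    io.write_matrix(cohort.signal, out / "signal.tsv", index_label="peak_id")
    io.write_matrix(cohort.expression, out / "expression.tsv", index_label="gene_id")
    io.write_table(cohort.samples, out / "samples.tsv")
    io.write_table(cohort.tss, out / "tss.tsv")
    io.write_table(cohort.peaks, out / "consensus_peaks.tsv")
    manifest.update(
        signal="signal.tsv", expression="expression.tsv", samples="samples.tsv",
        tss="tss.tsv", peaks="consensus_peaks.tsv", truth="truth.json",
        config="config.yaml",
    )
    t = cohort.truth
    io.write_json(
        {
            "subgroup": t.subgroup,
            "tumor_specific": t.tumor_specific,
            "normal_specific": t.normal_specific,
            "hvp": t.hvp,
            "se_regions": t.se_regions.assign(
                members=t.se_regions["members"].apply(list)
            ).to_dict(orient="list"),
            "links": [list(x) for x in t.links],
            "regulators": t.regulators,
            "bipartite_edges": [list(x) for x in t.bipartite_edges],
            "core_clique": t.core_clique,
            "gi_genes": t.gi_genes,
            "gii_genes": t.gii_genes,
        },
        out / "truth.json",
    )
    (out / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(cohort.config), sort_keys=True)
    )
    io.write_json(manifest, out / "manifest.json")
    return manifest


def read_fixtures(out_dir: str | Path) -> Cohort:
    out = Path(out_dir)
    cfg = SyntheticConfig.from_yaml(out / "config.yaml")
    raw = io.read_json(out / "truth.json")
    se = pd.DataFrame(raw["se_regions"])
    se["members"] = se["members"].apply(tuple)
    truth = SyntheticTruth(
        subgroup=raw["subgroup"],
        tumor_specific=raw["tumor_specific"],
        normal_specific=raw["normal_specific"],
        hvp=raw["hvp"],
        se_regions=se,
        links=[tuple(x) for x in raw["links"]],
        regulators=raw["regulators"],
        bipartite_edges=[tuple(x) for x in raw["bipartite_edges"]],
        core_clique=raw["core_clique"],
        gi_genes=raw["gi_genes"],
        gii_genes=raw["gii_genes"],
    )
    return Cohort(
        config=cfg,
        peaks=io.read_table(out / "consensus_peaks.tsv"),
        signal=io.read_matrix(out / "signal.tsv"),
        expression=io.read_matrix(out / "expression.tsv"),
        samples=io.read_table(out / "samples.tsv"),
        tss=io.read_table(out / "tss.tsv"),
        truth=truth,
    )


def fixture_digest(out_dir: str | Path) -> str:
    """SHA256 over every fixture file (byte-identity check across runs)."""
    out = Path(out_dir)
    h = hashlib.sha256()
    for path in sorted(p for p in out.rglob("*") if p.is_file()):
        h.update(str(path.relative_to(out)).encode())
        h.update(path.read_bytes())
    return h.hexdigest()
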