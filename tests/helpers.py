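"""Shared simulation helpers for fine-mapping and enrichment tests."""

import numpy as np

from gwaspost.finemap import Region
from gwaspost.simulate import ar1_matrix


def simulate_single_causal_regions(
    n_regions,
    n_variants=40,
    rho=0.4,
    gamma=np.log(3.0),
    prior_var=0.04,
    se=0.08,
    coverage=0.2,
    seed=0,
):
    """Regions with exactly one causal variant drawn from the annotation-
    tilted prior, marginal effects projected through AR(1) LD with matched
    noise. Returns (regions, causal ids) — the matched-generator setup for
    credible-set calibration and enrichment recovery."""
    rng = np.random.default_rng(seed)
    R = ar1_matrix(n_variants, rho)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(n_variants))
    regions, causal = [], []
    for i in range(n_regions):
        a = (rng.random(n_variants) < coverage).astype(float)
        w = np.exp(gamma * a)
        w /= w.sum()
        v = int(rng.choice(n_variants, p=w))
        b = np.zeros(n_variants)
        b[v] = rng.normal(0.0, np.sqrt(prior_var))
        beta_hat = R @ b + se * (L @ rng.standard_normal(n_variants))
        z = beta_hat / se
        from gwaspost.meta import two_sided_p

        p, _ = two_sided_p(z)
        regions.append(
            Region(
                region_id=f"r{i}",
                chrom="1",
                rsids=[f"v{i}_{j}" for j in range(n_variants)],
                beta=beta_hat,
                se=np.full(n_variants, se),
                p=np.atleast_1d(p),
                annotations={"t": a.astype(int)},
            )
        )
        causal.append(f"v{i}_{v}")
    return regions, causal


def brute_force_prioritization(matrix, predictors):
    """Loop-based consensus oracle: per locus, per-gene evidence sums,
    argmax set, tier. Independent of the package implementation."""
    out = {}
    for locus in sorted(set(matrix["LOCUS_ID"])):
        sub = matrix[matrix["LOCUS_ID"] == locus]
        sums = {}
        for _, row in sub.iterrows():
            sums[row["GENE"]] = sum(int(row[p]) for p in predictors)
        best = max(sums.values())
        nominees = sorted(g for g, s in sums.items() if s == best and best > 0)
        out[locus] = {"nominees": nominees, "n": best if nominees else 0}
    return out
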