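"""Shared fixtures: small simulated panels and VCF fixtures on disk."""

import numpy as np
import pytest

import lapaint as lp


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated experiment shared by read-only tests."""
    cfg = lp.SimulationConfig(n_sites=3000, seed=11, n_ref_hap=20)
    rng = cfg.rng()
    panel, haps, true_freq = lp.simulate_panel(cfg, rng)
    sample, truth = lp.simulate_admixed(cfg, true_freq, rng)
    return {"cfg": cfg, "panel": panel, "haps": haps,
            "true_freq": true_freq, "sample": sample, "truth": truth}


@pytest.fixture()
def vcf_pair(tmp_path):
    """Two single-population VCFs plus the same data as one multi-sample VCF."""
    cfg = lp.SimulationConfig(n_sites=120, seed=5, n_ref_hap=8)
    rng = cfg.rng()
    panel, haps, _ = lp.simulate_panel(cfg, rng)
    per_pop = {}
    for pop, h in haps.items():
        samples = [
            lp.PhasedSample(
                sites=panel.sites, a0=h[j], a1=h[j + 1],
                phased=np.ones(len(panel.sites), dtype=bool),
                sample_id=f"{pop}_s{j // 2}",
            )
            for j in range(0, h.shape[0] - 1, 2)
        ]
        path = tmp_path / f"{pop}.vcf"
        lp.write_vcf(samples, path)
        per_pop[pop] = path
    multi, popmap = lp.write_reference_vcf(haps, panel.sites,
                                           tmp_path / "ref.vcf")
    return {"per_pop": per_pop, "multi": multi, "popmap": popmap,
            "panel": panel, "cfg": cfg}


def write_vcf_text(path, records, samples=("S1",)):
    """Write a minimal VCF by hand for malformed/edge-case fixtures."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write("##contig=<ID=1,length=1000000>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return path
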