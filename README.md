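# ifacevol

Structure-conditioned molecular evolution of multi-subunit protein
complexes.

Respiratory-chain complexes are built from subunits encoded by two genomes:
a handful of mtDNA-encoded core chains surrounded by nuclear-encoded
partners.  Whether the mtDNA-encoded residues that touch nuclear-encoded
chains evolve faster (interface optimisation) or slower (purifying
constraint) than the rest of the molecule is a question that is easy to get
wrong: contact status is confounded with burial, interface membership and
proximity to prosthetic groups.  `ifacevol` is a pipeline for asking that
question carefully.  It is aimed at molecular evolution researchers with a
codon alignment per subunit, a crystal structure of the complex, and a
phylogeny.

The pipeline:

1. **Classify** every residue of the mtDNA-encoded chains by the structure:
   `MT_NU_CONTACT` (< 4 Å heavy-atom distance to a nuclear-encoded chain),
   `MT_MT_CONTACT` (contacts only mtDNA-encoded chains),
   `EXPOSED_NONCONTACT` (further split by interface membership,
   ΔASA = ASA_isolated − ASA_complex > 0), and `BURIED_NONCONTACT`
   (relative solvent accessibility < 0.05).  ASA is Shrake–Rupley.
2. **Sort** codon alignment columns into those classes through a reference
   taxon's ungapped codons.
3. **Contrast rates.**  For each class, ΣdN — the sum of pairwise
   nonsynonymous divergences dN (YN00-style κ/F3×4-weighted counting, or
   NG86) over all sequence pairs — and interaction ratios
   R = ΣdN(class A)/ΣdN(class B), with R > 1 meaning A evolves faster.
4. **Test** whether a class is exceptional by an empirical null: B = 10⁴
   random codon subsets of the same size, add-one tail probabilities.
5. **Fit codon models** on the fixed tree: M0 (single ω = dN/dS) for branch
   lengths, then fixed-sites fits with one ω per structural class (shared
   κ), an M1a-vs-M2a likelihood-ratio test for positive selection
   (χ², 2 df), and per-branch dN apportioned by expected Markov counts,
   summarised as the per-branch difference dN_Mt–nu − dN_Mt–mt.
6. **Relate to stability**: per-class ΔΔG statistics from an external
   alanine-scan table (Welch contrasts) and the Pearson correlation between
   per-class ΣdN and mean ΔΔG.

Every stage is also runnable against synthetic data with planted ground
truth (toy complexes, simulated trees and GY94 codon alignments with
class-specific ω, class-dependent ΔΔG tables), which is how the test suite
validates the pipeline end to end.

## Worked example

Run the bundled synthetic study: a 4-chain complex (2 mtDNA-encoded), 100
residues per chain, 6 taxa, where chain A's exposed noncontact surface is
planted as exceptionally conserved (ω = 0.04) while chain B's is the most
variable class (ω = 0.40):

```python
from ifacevol.pipeline import run_synthetic_study

res = run_synthetic_study("small", seed=1, out_dir="study")
rep = res["report"]
for chain in ("A", "B"):
    ratios = rep["divergence"][chain]["interaction_ratios"]
    null = rep["null"][chain]
    omega = rep["ml"][chain]["fixed_sites"]["omega"]
    print(chain, round(ratios["mt_nu_contact_vs_exposed_noncontact"], 3),
          round(null["p_lower"], 3), round(null["p_upper"], 3),
          {k: round(v, 3) for k, v in omega.items()})
```

prints

```
A 3.743 0.026 0.976 {'EXPOSED_NONCONTACT': 0.049, 'MT_MT_CONTACT': 0.039,
                     'BURIED_NONCONTACT': 0.196, 'MT_NU_CONTACT': 0.252}
B 0.497 0.992 0.01  {'EXPOSED_NONCONTACT': 0.405, 'MT_MT_CONTACT': 0.08,
                     'MT_NU_CONTACT': 0.321, 'BURIED_NONCONTACT': 0.108}
```

Reading chain A: contacts with nuclear-encoded chains accumulate 3.7× the
nonsynonymous divergence of the exposed noncontact surface (R > 1), but the
resampling null shows why — that surface is exceptionally *conserved*
(lower-tail p = 0.026), not the contacts exceptionally fast; the
fixed-sites ω̂ = 0.049 for the exposed class (planted 0.04) confirms strong
purifying selection.  Chain B shows the default ordering: its exposed
surface is the most variable class (upper-tail p = 0.010, ω̂ = 0.405
against a planted 0.40), and contacts are slower (R = 0.497 < 1).  In both
chains the per-branch difference dN_Mt–nu − dN_Mt–mt is positive on ≥ 89%
of branches (report key `branch_dn_diff`): intra-genome contacts are the
most constrained class, consistently across lineages.

The same stages run on real inputs from a YAML config
(`ifacevol run --config cfg.yaml --out results/`), or individually:
`ifacevol classify`, `sort`, `sumdn`, `nullboot`, `ml`, `stability`,
`synth`.

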