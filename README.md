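# phypif

A quantitative model of how light, sensed by phytochrome B (PhyB), is
relayed through the transcription factor PIF3 to the nuclear genes that
build the chloroplast's plastid-encoded RNA polymerase machinery — the
sigma factors (SIGs), the polymerase-associated proteins (PAPs) and PRIN2.
The package is aimed at plant systems biologists who want to simulate,
fit, or probe this signalling cascade, and at anyone who needs a compact,
fully testable example of model reduction in a photoreceptor network.

## The model

**Phytochrome switch.** PhyB interconverts between an inactive Pr and an
active Pfr form; in light the two equilibrate fast with ratio
K<sub>Pfr</sub> (≈ 7 in red light, so the Pfr fraction is
R<sub>Pfr</sub> = K<sub>Pfr</sub>/(1+K<sub>Pfr</sub>) = 0.875). Because
Pfr decays faster than Pr, total PhyB — scaled by its dark stationary
level — obeys

    d[PhyB]/dt = γ_Pr (1 − Q_Pfr [PhyB]),   [PhyB](0) = 1,

with Q<sub>Pfr</sub> = (1 + Γ<sub>Pfr</sub>K<sub>Pfr</sub>)/(1 + K<sub>Pfr</sub>)
(= 8.75 at defaults), solved in closed form. The pooled rate
Q<sub>Pfr</sub>γ<sub>Pr</sub> = 3 ln 2 /day is pinned by the observed
~8-hour half-life of PhyB in red light.

**PIF3 degradation.** Pfr dimers phosphorylate PIF3 dimers, which the 26S
proteasome removes. The three-variable mechanism reduces, under fast
dimerization and fast degradation of the phosphorylated pool, to

    d[PIF]/dt = γ_PIF (1 − [PIF] − R_PP [PhyB]² [PIF]²),

with interaction strength R<sub>PP</sub> = 350 and
γ<sub>PIF</sub>R<sub>PP</sub> = 96/day (the measured ~15-minute PIF3
half-life in red light). A closed-form fast+slow approximation of the
whole time course is provided alongside the numeric solution.

**Repressed gene expression.** A PIF3-repressed gene X with promoter
dissociation constant K<sub>PIF</sub> (relative to the dark PIF3 level)
follows

    d[X]/dt = γ (φ(t) − [X]),   φ = (K_PIF + 1)/(K_PIF + [PIF]²),

with all transcripts sharing a 6-hour half-life (γ = 4 ln 2 /day), leaving
K<sub>PIF</sub> as the single gene-specific parameter. It is fitted per
gene by weighted least squares; phyB-deficient mutants are modelled by
scaling the PhyB trajectory by a factor q (≈ 1/4).

The package also scans promoter FASTA for the PIF3 binding motifs G-box
(CACGTG) and PBE-box (CACATG) on both strands with ATG-anchored offsets,
and generates seeded synthetic data (qPCR-style fold-change replicates,
decay curves, motif-planted promoters) so the whole pipeline is testable
without downloads.

## Worked example

```python
import numpy as np
from phypif import DEFAULT_GENES, ModelConfig, simulate_genes, peak_metrics

grid = np.linspace(0.0, 7.0, 701)
traj = simulate_genes(DEFAULT_GENES, ModelConfig(), grid)
print(f"PhyB(1 d) = {traj['phyb'][100]:.3f}   PIF3 min = {traj['pif'].min():.3f}")
for g, gene in DEFAULT_GENES.items():
    t_pk, x_pk = peak_metrics(traj, g)
    print(f"{g:6s} K_PIF={gene.K_PIF:.2f}  peak {x_pk:5.2f}x at {t_pk:.2f} d")
```

prints

```
PhyB(1 d) = 0.225   PIF3 min = 0.084
SIG2   K_PIF=0.32  peak  3.77x at 1.18 d
SIG6   K_PIF=0.22  peak  4.93x at 1.12 d
PAP1   K_PIF=0.35  peak  3.55x at 1.20 d
PAP2   K_PIF=0.12  peak  7.81x at 1.02 d
PAP5   K_PIF=0.48  peak  2.89x at 1.25 d
PRIN2  K_PIF=0.09  peak  9.75x at 0.97 d
```

Total PhyB has dropped to 0.225 of its dark level after one day of light;
PIF3 collapses to 8% of its dark level within ~7 hours and then partially
recovers; every repressed gene shows the generic light-induction profile —
a 3–10-fold peak within the first day, larger for stronger dark repression
(smaller K<sub>PIF</sub>), followed by a slow decline toward its stationary
level.

The same pipeline is available from the shell:

```sh
phypif synthesize --seed 1 --out-prefix syn     # seeded fixtures
phypif fit syn_expression.csv --out fits.json   # per-gene K_PIF estimates
phypif scan-motifs syn_promoters.fasta          # G-box/PBE-box hits
phypif simulate --days 7 --out trajectories.csv
```

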