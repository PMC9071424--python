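# sumoscreen

Analysis pipelines for identifying non-covalent poly-SUMO receptors and
mapping their SUMO-binding surfaces. The package implements five quantitative
stages, each exercisable end to end on seeded synthetic data:

| stage       | what it does |
|-------------|--------------|
| `arrays`    | Protein-microarray hit calling: per-spot S/N, control normalization, duplicate averaging, two-stage loess detrending (print-tip M-vs-A, then spatial), mean + k·SD thresholding of M-values. |
| `footprint` | Covalent-labelling footprinting: in-silico tryptic digest, fractional modification P = A(lab)/(A(lab)+A(unlab)), Welch t-test masking/unmasking calls, residue-level class maps, structure-colouring attribute files. |
| `nmr`       | Titration mapping: intensity-ratio and combined-CSP threshold ladders (eight named built-ins, custom ladders loadable from config), rank/colour per residue. |
| `motif`     | Proteome scanning for the XRCC4-like SIM pattern `K[SDE][VLI][DES][FVLI]`, acidic-context annotation, one-sided Fisher enrichment of a receptor set. |
| `binding`   | Single-site equilibrium fits (hyperbolic and ligand-depletion quadratic isotherms) with multi-start initialization, plus reporter repair-frequency normalization. |
| `synthetic` | Seeded generators for all of the above with machine-readable truth files. |

## CLI

Everything is reachable through one entry point:

```sh
# generate synthetic inputs for any stage (deterministic per seed)
sumoscreen simulate array    --seed 1 --out sim/array
sumoscreen simulate binding  --seed 1 --out sim/binding

# analyse
sumoscreen arrays call-hits --bound sim/array/bound.gpr --mock sim/array/mock.gpr \
    --k 1.0 --span-printtip 0.75 --span-spatial 0.3 --out results/screen
sumoscreen footprint quantify --fasta target.fasta --areas areas.csv --alpha 0.05 --out results/fp
sumoscreen nmr map --peaks peaks.csv --ladder xrcc4_msumo2 --out results/nmr
sumoscreen motif scan --fasta proteome.fasta --receptors receptors.txt \
    --universe universe.txt --out results/motif
sumoscreen binding fit --curve sim/binding/curve.csv --model depletion \
    --target-conc 5 --out results/kd
```

Every command writes a `*.manifest.json` recording the resolved parameters,
input checksums and outputs. Exit codes: 0 success, 2 validation error,
3 degenerate data.

Input formats are plain text: GPR-dialect tab-delimited scan files
(ATF header; columns Block, Row, Column, X, Y, ID, Name, F median, B median,
B SD, Flags), CSV peak/area/curve tables, FASTA, and one-ID-per-line lists.

## Library use

```python
from sumoscreen import arrays, synthetic

bound, mock, truth = synthetic.gen_array(synthetic.ArrayConfig(seed=1, n_spikes=20,
                                                               spike_effect=0.5))
m = arrays.compute_m_values(bound, mock)
calls = arrays.call_hits(m, k=1.0)
print(calls.threshold, calls.unique_candidates[:5])
```
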