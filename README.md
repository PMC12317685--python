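# pepmat

Training amino-acid substitution matrices to discriminate, locate and cluster
functional peptide sets.

## The problem

Some groups of functional peptides — the motivating case is the tooth enamel
pellicle, the layer of salivary peptides that binds directly to enamel
hydroxyapatite — are short (8–36 residues), few (tens), heterogeneous in
length, and share no alignable motif. Profile methods (PSSMs, HMMs) need a
multiple alignment that cannot be built; with so few sequences, generic
classifiers overfit. What such sets do carry is a diffuse, chemistry-level
signal: which residue types substitute for which within a functional context.
That is exactly what an amino-acid substitution matrix encodes.

`pepmat` learns a 20×20 integer substitution matrix **M** (entries in
[−19, 19], rows = query residue, columns = dataset residue, asymmetric
allowed) that separates a functional peptide set *F* from a control set *N*
under global (Needleman–Wunsch) alignment with affine gaps. The set-level
similarity is

    TSS(A, B) = mean over pairs (a, b) of  nw_score(a, b) / meanlen(a, b)

(self pairs excluded within a set), and training maximizes by default

    TSSF = TSS(F,F) + TSS(N,N) − TSS(F,N) − TSS(N,F)

via an exhaustive integer gap-penalty grid search followed by greedy and
modified Monte Carlo refinement of whole matrix columns and rows. Assessment
is leave-one-protein-out — scoring a peptide never uses any peptide from the
same source protein — summarized by ROC AUC, precision–recall, an MCC curve
over 101 thresholds (whose maximum fixes the operational cutoff), and a
one-tailed Welch *t*-test. The trained matrix then scores new peptides, scans
whole proteins for candidate binding regions with matched-length sliding
windows, and clusters the peptides into mechanistic subgroups via a
thresholded similarity network with center-star alignments per cluster.

See `docs/methods.md` for the full model, parameter meanings and defaults,
and the synthetic data generator's scope.

## Worked example

Generate a planted-motif dataset (three families of chemically
interchangeable position classes: carboxyl/amide, alternating hydroxyl,
proline-rich), train a matrix from an identity start, and benchmark it:

```python
import pepmat as pm

spec = pm.SyntheticSpec(n_families=3, peptides_per_family=(7, 7, 6),
                        substitution_noise=0.2, seed=11)
functional, control, proteins = pm.synthetic_dataset(spec)

start = pm.identity_matrix()
trained, gaps, trace = pm.train_matrix(functional, control, start,
                                       pm.TrainingConfig(seed=1837))

before = pm.loo_benchmark(functional, control, start,
                          pm.grid_search_gaps(functional, control, start))
after = pm.loo_benchmark(functional, control, trained, gaps)
print(f"gaps open={gaps.open} extend={gaps.extend}")
print(f"AUC {before.auc:.3f} -> {after.auc:.3f}, "
      f"best MCC {after.best_mcc:.2f} @ threshold {after.best_threshold:.2f}")
```

which prints

```
gaps open=-1 extend=-1
AUC 0.978 -> 0.985, best MCC 0.95 @ threshold 0.36
```

The 20 functional and 20 control peptides are scored leave-one-protein-out;
training lifts the AUC and the MCC maximum marks the score cutoff that best
separates the classes — the same cutoff used to threshold the peptide
similarity network:

```python
network = pm.build_network(functional, trained, gaps, threshold=after.best_threshold)
clusters, singletons = pm.extract_clusters(network)
msa = pm.center_star_msa(pm.PeptideSet([functional[i] for i in clusters[0]]),
                         trained, gaps)
```

The same objects drive the command line: `pepmat simulate`, `pepmat train`,
`pepmat benchmark`, `pepmat survey` (rank many AAindex-format starting
matrices), `pepmat scan` (per-residue protein profiles), `pepmat cluster`,
`pepmat decoys`, `pepmat score` and `pepmat align`. Every run writes its
resolved configuration and a JSON-lines log next to its outputs.

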