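# epinet

Sparse Walsh-Hadamard (WH) spectral regularization of sequence-to-fitness
models. Any real-valued function of `d` binary sites is uniquely a
multilinear polynomial over ±1 inputs; its coefficients are the epistatic
interaction coefficients. `epinet` provides:

- **`epinet.spectral`** — encodings (binary sites, one-hot amino-acid
  blocks), the fast WH transform in both multilinear and unitary scale,
  pseudo-Boolean evaluation, variance-explained curves, spectrum I/O.
- **`epinet.sparse`** — sublinear sparse WH recovery: sparse-graph-code
  subsampling plans, bin observations under delayed offsets, singleton
  detection, and the iterative peeling decoder. Recovers a k-sparse
  spectrum from `C·(d+1)·2^b` queries instead of `2^d`.
- **`epinet.nn`** — the reference regression network (four dense layers
  `d×fd, fd×fd, fd×d, d×1` with batch normalization, leaky ReLU,
  Xavier-uniform init, Adam) with hand-rolled reverse-mode gradients so
  arbitrary scalar losses of the predictions can drive training.
- **`epinet.en`** — exact spectral regularization: composite loss
  `Σ(y−g(x))² + α‖U g(X)‖₁` with the penalty evaluated on the full
  `2^d` enumeration (admissible for `d ≤ 25`), trained with Adam and
  validation early stopping.
- **`epinet.ens`** — the scalable variant: ADMM decoupling into an SGD
  model step penalized at subsampled points, a peeling-based sparse
  spectrum step with the `l0` hard-threshold prox (`u² ≥ 2α/ρ`), and a
  dual update. No object of size `2^d` is ever allocated, so any `d` works.
- **`epinet.landscapes`** — synthetic sparse-epistasis landscape
  generation (a few large coefficients plus many small ones, Gaussian
  observation noise), dataset sampling/splitting, Box-Cox preprocessing.
- **`epinet.evaluate`** — R², spectrum NMSE, the Lasso-over-WH-monomials
  baseline with OLS support debiasing, and the paired multi-seed
  benchmark orchestrator.

## CLI

```sh
epinet simulate --d 13 --k-large 5 --k-small 20 --sigma 1.0 --n 2120 \
    --seed 0 --out data.csv --truth-out truth.tsv
epinet transform --landscape landscape.csv --d 8 --out spectrum.tsv
epinet recover-spectrum --data values.csv --d 13 --k 25 --b 6 --out rec.tsv
epinet train-en  --data data.csv --alpha 0.1 --out run
epinet train-ens --data data.csv --alpha 1.0 --rho 0.01 --k 25 --b 6 --out run
epinet baseline-lasso --data data.csv --max-order 2 --out lasso.tsv
epinet benchmark --config bench.yaml --out report.json
epinet evaluate --estimated rec.tsv --truth truth.tsv
```

Datasets are plain CSV with `sequence` (bitstring over mutation sites:
`0` = reference, `1` = mutated) and `fitness` columns. Spectra are TSV
with `mask` (bitstring, site 0 first), `order`, `coefficient`, `scale`.

## Conventions

- Subset masks are integers; bit `i` ↔ site `i` (0-based, first site =
  bit 0). Landscape entry `j` is the value at the ±1 vector with
  `x_i = +1` iff bit `i` of `j` is 0 (reference state = +1).
- Stored spectra default to the multilinear scale (the literal polynomial
  coefficients); the unitary scale differs by exactly `2^{d/2}` and is
  used inside the training losses.
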