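#!/usr/bin/env python
"""Optional real-data benchmark (requires downloaded study data).

This script is NOT part of the test suite: it needs the sister-cell
scRNA-seq count matrix (SRA BioProject PRJNA882056, preprocessed to a
cells x genes table) and its pedigree/covariate annotations, which must
be downloaded and assembled locally.  Given those inputs it reports:

* the number of genes passing the mean-expression filter (expected to be
  near 1177 for the 124-cell sister dataset),
* the number of BH-significant memory genes (expected near 55),
* the overlap between the memory genes and the 55 most-variable genes
  (expected near 16).

Because the normalization is a contract-level re-implementation of the
regularized NB-residual approach rather than a bit-compatible clone,
exact agreement is not guaranteed.

Usage:
    python benchmarks/real_data.py --counts counts.tsv --pedigree ped.tsv \
        [--covariates cov.csv --covariate batch --covariate day ...]
"""

import argparse
import sys
from pathlib import Path


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__,
                                 formatter_class=argparse.RawDescriptionHelpFormatter)
    ap.add_argument("--counts", required=True,
                    help="cells x genes UMI count matrix (TSV or MTX directory)")
    ap.add_argument("--pedigree", required=True,
                    help="pedigree TSV (cell_id, family_id, sister_pair_id, ...)")
    ap.add_argument("--covariates", default=None, help="per-cell covariate CSV")
    ap.add_argument("--covariate", action="append", default=[],
                    help="covariate column to regress out (repeatable)")
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args(argv)

    for path in (args.counts, args.pedigree):
        if not Path(path).exists():
            print(f"error: input not found: {path}", file=sys.stderr)
            return 2

    import sistermem as sm
    from sistermem import io as smio
    from sistermem.pipeline import RunConfig, _rnaseq_inputs

    cfg = RunConfig(
        workflow="gen1_rnaseq", outdir=".", counts_path=args.counts,
        pedigree_path=args.pedigree, covariates_path=args.covariates,
        covariates=tuple(args.covariate),
    )
    adata, ped, counts = _rnaseq_inputs(cfg, generation=1)
    print(f"cells after QC and orphan removal: {adata.n_obs}")
    print(f"genes passing the mean-expression filter: {adata.n_vars}")

    results = sm.detect_memory_genes(adata, alpha=args.alpha)
    memory = results.index[results["memory"]]
    print(f"memory genes (BH < {args.alpha}): {len(memory)}")

    top = sm.most_variable_genes(adata, min(55, adata.n_vars))
    overlap = len(set(memory) & set(top))
    print(f"overlap of memory genes with the {len(top)} most-variable genes: "
          f"{overlap}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
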