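"""Exception hierarchy for the coelute pipeline."""


class CoeluteError(Exception):
    """Base class for all coelute errors."""


class ParameterError(CoeluteError, ValueError):
    """A parameter is outside its documented range."""


class ParseError(CoeluteError, ValueError):
    """A text artifact violates its schema; message carries line context."""


class UnmappedProteinError(CoeluteError, KeyError):
    """PSM records reference proteins absent from the orthogroup map."""

    def __init__(self, proteins):
        self.proteins = sorted(proteins)
        super().__init__(
            f"{len(self.proteins)} protein(s) not in the orthogroup map: "
            + ", ".join(self.proteins[:10])
            + ("..." if len(self.proteins) > 10 else "")
        )


class UncalibratableError(CoeluteError, RuntimeError):
    """No score threshold attains the requested FDR target."""

    def __init__(self, target_fdr, best_fdr):
        self.target_fdr = target_fdr
        self.best_fdr = best_fdr
        super().__init__(
            f"no threshold attains FDR <= {target_fdr:.4g}; "
            f"best achievable FDR is {best_fdr:.4g}"
        )


class UndefinedResultError(CoeluteError, ValueError):
    """A statistic is undefined for the given input (e.g. empty denominator)."""
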