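"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when user-supplied data or configuration violates a contract."""


class UndefinedStatisticError(ArithmeticError):
    """Raised when a statistic has no defined value for the given table.

    Typical causes are a zero marginal relative frequency (CLQ undefined)
    or a degenerate chance-expected agreement of 1 (kappa undefined).
    Callers that assemble matrices of results catch this and report an
    explicit not-available marker instead of 0 or infinity.
    """
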