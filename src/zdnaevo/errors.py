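"""Exceptions shared across the toolkit."""


class DataError(ValueError):
    """Invalid input data (bad coordinates, malformed files, infeasible configs).

    The command-line layer maps this to exit code 1; anything else that
    propagates is a usage or programming error.
    """
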