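"""Exception hierarchy. Exit-code mapping lives in the CLI."""


class HaploqcError(Exception):
    """Base class for all package errors."""


class InputError(HaploqcError):
    """Invalid user input: bad parameter values, unreadable files, mismatched k."""


class ModelDegenerateError(HaploqcError):
    """The k-mer histogram carries too little structure to fit the mixture model."""


class GenerationError(HaploqcError):
    """A synthetic dataset could not be produced under the requested constraints."""


class ThreadingError(HaploqcError):
    """A protein alignment could not be back-threaded onto its coding sequences."""
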