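a
an
and
are
as
at
be
been
by
did
do
does
for
from
had
has
have
i
in
is
it
my
of
on
or
she
that
the
their
there
they
this
to
was
were
with
you
your
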