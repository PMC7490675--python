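# Minimal English stop-word list (swappable via PrepConfig.stopwords).
a
about
after
again
all
also
am
an
and
any
are
as
at
be
been
before
but
by
can
could
did
do
does
down
for
from
had
has
have
he
her
here
him
his
how
i
if
in
into
is
it
its
just
me
more
most
my
no
nor
not
now
of
off
on
once
only
or
other
our
out
over
own
say
she
should
so
some
such
than
that
the
their
them
then
there
these
they
this
those
through
to
too
under
until
up
was
we
were
what
when
where
which
while
who
why
will
with
would
you
your
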