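>Nsp1-S Nsp1 SG mutant (F,I,L,V -> S in the FG domain; TEV leader retained; extra S at 635)
MSKHHHHSGHHHTGHHHHSGSHHHTGENLYFQGSNSNTPQQNKTPSSSGTANNNSNTTNQ
NSSTGAGASGTGQSTSGSNNSAPNNTNNANSSSTPASGSNNTGNTASGNSNPTSNSSGSN
NSTTNTSGSNSAGTSSSGSSSAQQTKSNGTAGGNTSGSSSSSNNSTNSNTTKPASGGSNS
GGGNNTTPSSTGNANTSNNSSGATANANKPASSSGATTNDDKKTEPDKPASSSNSSSGNK
TDAQAPTTGSSSGSQSGGNKTSNEAAKPSSSSGSGSAGANPAGASQPEPTTNEPAKPASS
SGTATSDNKTTNTTPSSSSGAKSDENKAGATSKPASSSGAKPEEKKDDNSSKPASSSGAK
SNEDKQDGTAKPASSSGAKPAEKNNNETSKPASSSGAKSDEKKDGDASKPASSSGAKPDE
NKASATSKPASSSGAKPEEKKDDNSSKPASSSGAKSNEDKQDGTAKPASSSGAKPAEKNN
NETSKPASSSGAKSDEKKDGDASKPASSSGAKSDEKKDSDSSKPASSSGTKSNEKKDSGS
SKPASSSGAKPDEKKNDESSKPASSSGAKANEKKESDESKSASSSGSKPTGKEEGDGAKA
ASSSGAKPEEQKSSDTSKPASTSGAQKDNEKKTESTSC
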